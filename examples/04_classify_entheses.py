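"""Classify several attachment regions and export a comparison table.

Runs three preset comparisons end to end (phantom generation →
extraction → statistics → decision rules) and writes a one-row-per-
comparison CSV mirroring the published table layout.
"""

from pathlib import Path

from osteolacuna.classification import classify_enthesis, comparison_row, write_report
from osteolacuna.pipeline import run_preset_comparison

out = Path("scratch/examples")
out.mkdir(parents=True, exist_ok=True)

rows = []
for preset in ("desmognathus_umfe", "desmognathus_pmfe", "eusthenopteron_area1"):
    cmp, _, _ = run_preset_comparison(preset, seed=2, extents=(150, 150, 150))
    call = classify_enthesis(cmp)
    rows.append(comparison_row(preset, cmp, call))
    print(f"{preset:24s} ×{cmp.density_ratio:.2f}  orientation {cmp.orientation:9s} "
          f"volume {cmp.volume:9s} stellate {cmp.stellate:3s} -> {call.call}")

df = write_report(rows, json_path=out / "calls.json", csv_path=out / "calls.csv")
print(f"\nwrote {out / 'calls.csv'} ({len(df)} comparisons)")
# UMFE: fibres penetrate the bone directly (large stellate lacunae, shifted
# volumes); PMFE: attachment via the periosteum (compact lacunae of
# unchanged volume, orientation still perturbed)
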