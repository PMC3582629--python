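"""Decision rules mapping a region comparison to an enthesis call.

Two fibrous-enthesis signatures are distinguishable from the bone-cell
lacuna pattern alone:

* **UMFE** (unmediated fibrous enthesis) — tendon fibres penetrate the
  periosteal bone directly.  Signature: lacuna volumes *different*
  (larger) than the reference region, lacunae predominantly *stellate*,
  orientation *different*.
* **PMFE** (periosteally mediated fibrous enthesis) — fibres attach via
  the periosteum.  Signature: volumes *similar*, shape compact, but
  orientation still (slightly) *different*.

An elevated lacuna density supports either call but is deliberately not
a gating criterion: published UMFE examples span density ratios from
×1.04 to ×2.5, overlapping the PMFE range, so no ratio threshold can
separate the two.  Anything not matching either signature is returned
as *indeterminate* with per-criterion diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .comparison import ComparisonResult


@dataclass
class EnthesisCall:
    call: str  # "UMFE" | "PMFE" | "indeterminate"
    matched_signature: dict[str, bool]
    flags: list[str] = field(default_factory=list)


def classify_enthesis(cmp: ComparisonResult, density_elevated_cut: float = 1.0) -> EnthesisCall:
    """Classify an attachment region from its comparison result.

    Pure function of the comparison verdicts:

    * UMFE  ⇔ orientation different ∧ volume different ∧ stellate
    * PMFE  ⇔ orientation different ∧ volume similar ∧ not stellate
    * otherwise indeterminate.

    ``density_ratio >= density_elevated_cut`` (default 1.0, i.e. any
    elevation) is reported as a supporting flag only.
    """
    orientation_diff = cmp.orientation == "different"
    volume_diff = cmp.volume == "different"
    stellate = cmp.stellate == "yes"
    density_elevated = cmp.density_ratio >= density_elevated_cut
    signature = {
        "density_elevated": density_elevated,
        "orientation_different": orientation_diff,
        "volume_different": volume_diff,
        "stellate": stellate,
    }
    flags: list[str] = []
    if not density_elevated:
        flags.append(f"density ratio {cmp.density_ratio:.2f} below {density_elevated_cut:g}")
    if orientation_diff and volume_diff and stellate:
        call = "UMFE"
    elif orientation_diff and not volume_diff and not stellate:
        call = "PMFE"
    else:
        call = "indeterminate"
        if volume_diff and not stellate:
            flags.append("volume different but shape compact (unexplained volume increase)")
        if not orientation_diff and (volume_diff or stellate):
            flags.append("orientation similar despite other attachment signals")
        if stellate and not volume_diff:
            flags.append("stellate shape without a volume difference")
    return EnthesisCall(call=call, matched_signature=signature, flags=flags)


def comparison_row(name: str, cmp: ComparisonResult, call: EnthesisCall) -> dict:
    """One flat report row (mirrors a published-style comparison table)."""
    return {
        "comparison": name,
        "density_ratio": round(cmp.density_ratio, 3),
        "orientation": cmp.orientation,
        "volume": cmp.volume,
        "stellate": cmp.stellate,
        "call": call.call,
        "orientation_chi2": round(cmp.orientation_test.statistic, 3),
        "orientation_p": cmp.orientation_test.p_value,
        "volume_U": cmp.volume_test.statistic,
        "volume_p": cmp.volume_test.p_value,
        "stellate_fraction": round(cmp.stellate_fraction, 3),
        "flags": "; ".join(call.flags),
    }


def write_report(rows: list[dict], json_path: str | Path | None = None,
                 csv_path: str | Path | None = None) -> pd.DataFrame:
    """Export comparison rows as JSON and/or one-row-per-comparison CSV."""
    df = pd.DataFrame(rows)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=1, default=float))
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df
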