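"""End-to-end convenience drivers: phantom or scan cube → comparison → call.

These functions wire the modules together in the canonical order used
throughout the package: binarize → label (26-connectivity) → noise
filter → edge-cut filter → per-lacuna morphometry → cube profile →
two-cube statistics → enthesis call.
"""

from __future__ import annotations

import numpy as np

from . import synthetic
from .classification import EnthesisCall, classify_enthesis
from .comparison import ComparisonResult, compare_regions
from .extraction import (
    DEFAULT_CONNECTIVITY,
    DEFAULT_MIN_VOLUME_UM3,
    LabeledVolume,
    binarize,
    label_components,
    remove_edge_cut,
    remove_noise,
)
from .morphometry import (
    DEFAULT_STELLATE_THRESHOLD,
    LacunaRecord,
    RegionProfile,
    measure_all,
    profile_region,
)
from .volume_io import VoxelVolume


def extract_lacunae(
    vol: VoxelVolume,
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_volume_um3: float = DEFAULT_MIN_VOLUME_UM3,
    stellate_threshold: float = DEFAULT_STELLATE_THRESHOLD,
    binarize_method: str = "otsu",
    threshold: float | None = None,
    foreground: str = "bright",
) -> tuple[LabeledVolume, list[LacunaRecord]]:
    """Run the full extraction chain on one cube and measure survivors."""
    values = np.unique(vol.data)
    if np.all(np.isin(values, (0, 1))):
        mask = vol
    else:
        mask = binarize(vol, method=binarize_method, threshold=threshold, foreground=foreground)
    lab = label_components(mask, connectivity=connectivity)
    lab = remove_noise(lab, min_volume_um3=min_volume_um3)
    lab = remove_edge_cut(lab)
    records = measure_all(lab, stellate_threshold=stellate_threshold, origin_um=vol.origin_um)
    return lab, records


def profile_cube(vol: VoxelVolume, **kwargs) -> RegionProfile:
    """Extraction chain plus aggregation into a :class:`RegionProfile`."""
    _, records = extract_lacunae(vol, **kwargs)
    return profile_region(records, vol.voxel_size_um, vol.shape)


def run_preset_comparison(
    preset: str,
    seed: int,
    extents: tuple[int, int, int] = (200, 200, 200),
    render: bool = False,
    alpha: float = 0.05,
) -> tuple[ComparisonResult, RegionProfile, RegionProfile]:
    """Generate one attachment/reference phantom pair and compare them.

    With ``render=True`` the binary masks are first rendered to grayscale
    (blur + noise) and re-binarized, exercising the thresholding step; by
    default the clean masks feed the labeler directly.
    """
    att_cfg, ref_cfg = synthetic.build_preset(preset, extents=extents, seed=seed)
    profiles = []
    for cfg in (att_cfg, ref_cfg):
        mask, _truth = synthetic.generate_scene(cfg)
        vol = mask
        kwargs = {}
        if render:
            vol = synthetic.render_grayscale(
                mask, contrast=(200.0, 60.0), noise_sd=12.0, blur_sigma_um=0.5, seed=cfg.seed + 1
            )
            kwargs = dict(binarize_method="otsu", foreground="dark")
        profiles.append(profile_cube(vol, **kwargs))
    attachment, reference = profiles
    return compare_regions(attachment, reference, alpha=alpha), attachment, reference


def recovered_density_ratio(
    preset: str,
    seeds,
    extents: tuple[int, int, int] = (200, 200, 200),
) -> float:
    """Mean recovered density ratio of a preset pair over several seeds."""
    ratios = []
    for seed in seeds:
        cmp, _, _ = run_preset_comparison(preset, seed, extents=extents)
        ratios.append(cmp.density_ratio)
    return float(np.mean(ratios))


def classify_preset(preset: str, seed: int, **kwargs) -> tuple[EnthesisCall, ComparisonResult]:
    """One-shot phantom comparison and enthesis call for a preset."""
    cmp, _, _ = run_preset_comparison(preset, seed, **kwargs)
    return classify_enthesis(cmp), cmp
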