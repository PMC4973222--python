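"""Recall, false-positive rate and per-axis error benchmarking.

Localizations are matched to ground-truth emitters by greedy
ascending-distance assignment under an anisotropic metric that scales the
axial error by the (larger) axial tolerance:

    d = sqrt((dx^2 + dy^2) / r_lat^2 + dz^2 / r_ax^2) <= 1.

Recall is matched truths over all truths; the false-positive rate is
unmatched localizations over all localizations.  Per-axis error SDs are
sample standard deviations over matched pairs, pooled across frames.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admm import ADMMParams, admm_deconvolve
from .forward import EmitterSet, NoiseModel, simulate_frame
from .optics import PSFStack
from .refine import Localization, extract_candidates, refine_localizations

DEFAULT_LATERAL_RADIUS_NM = 100.0
DEFAULT_AXIAL_RADIUS_NM = 200.0


@dataclass
class MatchResult:
    """Greedy one-to-one assignment of localizations to ground truth."""

    pairs: list[tuple[int, int, float]]  # (loc index, truth index, distance)
    unmatched_locs: list[int]
    unmatched_truths: list[int]
    errors_nm: np.ndarray  # (n_pairs, 3) loc - truth per axis

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def _positions(locs) -> np.ndarray:
    if isinstance(locs, EmitterSet):
        return np.c_[locs.x_nm, locs.y_nm, locs.z_nm]
    if len(locs) and isinstance(locs[0], Localization):
        return np.array([[l.x_nm, l.y_nm, l.z_nm] for l in locs])
    return np.asarray(locs, dtype=float).reshape(-1, 3)


def match_localizations(
    locs,
    truth,
    lateral_radius_nm: float = DEFAULT_LATERAL_RADIUS_NM,
    axial_radius_nm: float = DEFAULT_AXIAL_RADIUS_NM,
) -> MatchResult:
    """Greedy nearest-pair matching under the anisotropic unit metric.

    Candidate pairs with scaled distance <= 1 are taken in ascending
    (distance, loc index, truth index) order, each loc and truth at most
    once; the tie-break makes the assignment deterministic.
    """
    if lateral_radius_nm <= 0 or axial_radius_nm <= 0:
        raise ValueError("match radii must be > 0")
    lp = _positions(locs)
    tp = _positions(truth)
    nl, nt = len(lp), len(tp)
    if nl == 0 or nt == 0:
        return MatchResult(
            [], list(range(nl)), list(range(nt)), np.zeros((0, 3))
        )
    diff = lp[:, None, :] - tp[None, :, :]
    d = np.sqrt(
        (diff[:, :, 0] ** 2 + diff[:, :, 1] ** 2) / lateral_radius_nm**2
        + diff[:, :, 2] ** 2 / axial_radius_nm**2
    )
    li, ti = np.nonzero(d <= 1.0)
    order = sorted(zip(d[li, ti], li, ti), key=lambda t: (t[0], t[1], t[2]))
    used_l: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for dist, i, j in order:
        if i in used_l or j in used_t:
            continue
        used_l.add(i)
        used_t.add(j)
        pairs.append((int(i), int(j), float(dist)))
    errors = np.array([lp[i] - tp[j] for i, j, _ in pairs]).reshape(-1, 3)
    return MatchResult(
        pairs=pairs,
        unmatched_locs=[i for i in range(nl) if i not in used_l],
        unmatched_truths=[j for j in range(nt) if j not in used_t],
        errors_nm=errors,
    )


def compute_metrics(match: MatchResult) -> tuple[float | None, float]:
    """(recall %, false-positive %) of one match result.

    Recall is undefined (None) with no true emitters; the FP rate of an
    empty localization list is 0.
    """
    n_truth = match.n_matched + len(match.unmatched_truths)
    n_locs = match.n_matched + len(match.unmatched_locs)
    recall = 100.0 * match.n_matched / n_truth if n_truth else None
    fp = 100.0 * len(match.unmatched_locs) / n_locs if n_locs else 0.0
    return recall, fp


def error_sds(match: MatchResult) -> tuple[float, float, float]:
    """Per-axis sample SD (nm) of localization errors over matched pairs."""
    if match.n_matched < 2:
        return (float("nan"),) * 3
    sds = np.std(match.errors_nm, axis=0, ddof=1)
    return tuple(float(s) for s in sds)


def pooled_match(matches: list[MatchResult]) -> MatchResult:
    """Pool matched pairs / unmatched counts across frames (indices lose
    meaning; only counts and errors are used downstream)."""
    errors = (
        np.concatenate([m.errors_nm for m in matches])
        if matches
        else np.zeros((0, 3))
    )
    pairs = [p for m in matches for p in m.pairs]
    ul = [i for m in matches for i in m.unmatched_locs]
    ut = [j for m in matches for j in m.unmatched_truths]
    return MatchResult(pairs, ul, ut, errors)


@dataclass
class BenchmarkReport:
    """Density-sweep metrics with full provenance."""

    table: pd.DataFrame
    config: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "config_hash": self.config_hash,
                    "rows": self.table.to_dict(orient="records"),
                },
                fh,
                indent=2,
            )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def localize_frame(
    frame,
    stack: PSFStack,
    params: ADMMParams | None = None,
    min_mass_frac: float = 0.02,
    merge_radius_vox: int = 2,
) -> list[Localization]:
    """Deconvolve -> extract -> refine one background-subtracted frame."""
    grid = admm_deconvolve(frame, stack, params)
    cands = extract_candidates(grid, min_mass_frac, merge_radius_vox)
    if not cands:
        return []
    return refine_localizations(frame, cands, grid, stack)


def density_sweep(
    stack: PSFStack,
    densities: list[float],
    n_frames: int | dict[float, int],
    seed: int,
    field_px: int = 64,
    noise: NoiseModel | None = None,
    params: ADMMParams | None = None,
    model=None,
    lateral_radius_nm: float = DEFAULT_LATERAL_RADIUS_NM,
    axial_radius_nm: float = DEFAULT_AXIAL_RADIUS_NM,
    photon_median: float = 3000.0,
) -> BenchmarkReport:
    """The density-sweep study: recall / FP / per-axis SD versus density.

    For each density, ``n_frames`` seeded frames (seeds derived from the
    master seed by fixed offsets) are simulated, localized, and matched;
    metrics are pooled over frames.  When a trained threshold ``model`` is
    supplied the report carries one row per (density, ml on/off), the ML-on
    row using only accepted localizations of the same pipeline run.
    """
    if not densities:
        raise ValueError("densities must be nonempty")
    from .mlfilter import apply_threshold  # local import, avoids cycle

    noise = noise or NoiseModel()
    params = params or ADMMParams(log_every=0)
    rows = []
    per_frame_errors = []
    for di, density in enumerate(densities):
        nf = n_frames[density] if isinstance(n_frames, dict) else n_frames
        matches_all: list[MatchResult] = []
        matches_ml: list[MatchResult] = []
        n_fail = 0
        for f in range(nf):
            frame_seed = seed + 1000 * di + f
            try:
                frame, truth = simulate_frame(
                    density,
                    stack,
                    field_px=field_px,
                    noise=NoiseModel(
                        noise.background, noise.read_noise_sd, noise.gain,
                        seed=frame_seed + 500,
                    ),
                    photon_median=photon_median,
                    seed=frame_seed,
                )
                work = subtract_background(frame)
                locs = localize_frame(work, stack, params)
            except Exception:  # pragma: no cover - per-frame robustness
                n_fail += 1
                continue
            matches_all.append(
                match_localizations(locs, truth, lateral_radius_nm, axial_radius_nm)
            )
            if model is not None:
                locs = apply_threshold(locs, model)
                kept = [l for l in locs if l.accepted]
                matches_ml.append(
                    match_localizations(kept, truth, lateral_radius_nm, axial_radius_nm)
                )
        for ml_on, matches in ((False, matches_all), (True, matches_ml)):
            if not matches:
                continue
            pooled = pooled_match(matches)
            recall, fp = compute_metrics(pooled)
            sx, sy, sz = error_sds(pooled)
            rows.append(
                {
                    "density_per_um2": density,
                    "ml": ml_on,
                    "recall_pct": recall,
                    "fp_pct": fp,
                    "sd_x_nm": sx,
                    "sd_y_nm": sy,
                    "sd_z_nm": sz,
                    "n_frames": len(matches),
                    "n_failed": n_fail,
                    "n_truth": pooled.n_matched + len(pooled.unmatched_truths),
                    "n_locs": pooled.n_matched + len(pooled.unmatched_locs),
                }
            )
    cfg = {
        "densities": list(densities),
        "n_frames": n_frames if not isinstance(n_frames, dict)
        else {str(k): v for k, v in n_frames.items()},
        "seed": seed,
        "field_px": field_px,
        "noise": {
            "background": noise.background,
            "read_noise_sd": noise.read_noise_sd,
            "gain": noise.gain,
        },
        "admm": {
            "mu": params.mu,
            "nu": params.nu,
            "iterations": params.iterations,
            "sparsity_weight": params.sparsity_weight,
        },
        "lateral_radius_nm": lateral_radius_nm,
        "axial_radius_nm": axial_radius_nm,
        "photon_median": photon_median,
        "with_ml": model is not None,
    }
    return BenchmarkReport(table=pd.DataFrame(rows), config=cfg)


def subtract_background(frame):
    """Return a background-subtracted copy of a frame.

    Uses the known noise-model background when available, otherwise the
    pixel median."""
    from .forward import Frame

    if frame.background_subtracted:
        return frame
    if frame.noise is not None:
        bg = frame.noise.gain * frame.noise.background
    else:
        bg = float(np.median(frame.pixels))
    out = Frame(
        pixels=frame.pixels - bg,
        pixel_size_nm=frame.pixel_size_nm,
        noise=frame.noise,
        background_subtracted=True,
        provenance={**frame.provenance, "background_subtracted": bg},
    )
    return out
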