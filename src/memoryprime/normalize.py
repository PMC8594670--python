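"""MA transformation, intensity-dependent lowess normalization, dye-swap
combination into per-biological-replicate log2 ratios.

Two-color intensities are re-expressed per probe as M = log2(red/green) and
A = (log2 red + log2 green)/2.  Intensity-dependent dye bias appears as a
smooth trend of M in A and is removed by subtracting a robust locally
weighted regression fit (lowess) of M on A within each array.  Dye-swap
pairs are then folded into a canonical orientation (positive M = higher in
the treated / later-named sample of the contrast) and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .synthio import ArraySet, StructuralError

INTENSITY_FLOOR = 1.0


@dataclass
class NormalizedArray:
    """Per-probe (M, A) for one array after within-array normalization."""

    array_id: str
    values: pd.DataFrame  # columns: probe_id, M, A

    def validate(self) -> None:
        if not np.isfinite(self.values["M"]).all():
            raise StructuralError(f"array {self.array_id!r}: non-finite M")
        if (self.values["A"] < 0).any():
            raise StructuralError(f"array {self.array_id!r}: negative A")


def ma_transform(arrays: ArraySet, array_id: str, floor: float = INTENSITY_FLOOR) -> pd.DataFrame:
    """Raw MA values for one array: M = log2(red/green), A = mean log2 intensity.

    Intensities are clipped at `floor` (default 1.0) so logs stay defined.
    """
    sub = arrays.array_intensities(array_id)
    red = np.maximum(sub["red"].to_numpy(dtype=float), floor)
    green = np.maximum(sub["green"].to_numpy(dtype=float), floor)
    if (red <= 0).any() or (green <= 0).any():
        raise StructuralError(f"array {array_id!r}: non-positive intensity after floor")
    lr, lg = np.log2(red), np.log2(green)
    return pd.DataFrame({"probe_id": sub["probe_id"], "M": lr - lg, "A": 0.5 * (lr + lg)})


def lowess_normalize(
    M: np.ndarray,
    A: np.ndarray,
    span: float = 0.3,
    iterations: int = 3,
) -> np.ndarray:
    """Subtract a robust lowess fit of M on A; returns the normalized M.

    span is the lowess fraction (window = span * n points); iterations are
    robustness reweighting passes.  Requires >= 50 probes and a window of at
    least 4 points.
    """
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    if M.shape != A.shape or M.ndim != 1:
        raise ValueError("M and A must be 1-D arrays of equal length")
    n = len(M)
    if n < 50:
        raise ValueError(f"need >= 50 probes for lowess normalization, got {n}")
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    if int(span * n) < 4:
        raise ValueError(
            f"span {span} covers only {int(span * n)} of {n} probes; use a larger span"
        )
    if np.ptp(A) == 0.0:
        # degenerate abscissa: local regression reduces to the mean
        return M - M.mean()
    delta = 0.001 * np.ptp(A)
    fit = _sm_lowess(M, A, frac=span, it=iterations, delta=delta, return_sorted=False)
    return M - fit


def normalize_array(
    arrays: ArraySet,
    array_id: str,
    span: float | None = 0.3,
    iterations: int = 3,
    floor: float = INTENSITY_FLOOR,
) -> NormalizedArray:
    """MA-transform one array and (unless span is None) lowess-normalize it."""
    ma = ma_transform(arrays, array_id, floor=floor)
    if span is not None:
        ma = ma.assign(M=lowess_normalize(ma["M"].to_numpy(), ma["A"].to_numpy(), span, iterations))
    out = NormalizedArray(array_id=array_id, values=ma)
    out.validate()
    return out


def dye_swap_combine(
    pair: tuple[NormalizedArray, NormalizedArray],
    design: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Fold one dye-swap pair into per-transcript canonical log2 ratios.

    The swapped array's M is negated into the canonical orientation
    (treatment over reference), the two arrays are averaged per probe, and
    probe-level values are aggregated to transcripts by arithmetic mean.
    Returns columns contrast_id, transcript_id, bio_rep, M.
    """
    first, second = pair
    rows = design.set_index("array_id")
    try:
        meta = [rows.loc[a.array_id] for a in pair]
    except KeyError as exc:
        raise StructuralError(f"array {exc.args[0]!r} absent from design") from None
    if meta[0]["contrast_id"] != meta[1]["contrast_id"] or meta[0]["bio_rep"] != meta[1]["bio_rep"]:
        raise StructuralError(
            f"arrays {first.array_id!r} and {second.array_id!r} are not a "
            "dye-swap pair (contrast/bio_rep mismatch)"
        )
    if bool(meta[0]["dye_swapped"]) == bool(meta[1]["dye_swapped"]):
        raise StructuralError(
            f"arrays {first.array_id!r} and {second.array_id!r} share the same "
            "dye orientation; a swap partner is missing"
        )

    frames = []
    for arr, m in zip(pair, meta):
        v = arr.values[["probe_id", "M"]].copy()
        if bool(m["dye_swapped"]):
            v["M"] = -v["M"]
        frames.append(v.set_index("probe_id")["M"])
    if not frames[0].index.sort_values().equals(frames[1].index.sort_values()):
        raise StructuralError(
            f"arrays {first.array_id!r} and {second.array_id!r} cover different probes"
        )
    combined = 0.5 * (frames[0] + frames[1].reindex(frames[0].index))

    ann = annotation.set_index("probe_id")["transcript_id"]
    missing = combined.index.difference(ann.index)
    if len(missing):
        raise StructuralError(f"unannotated probes, e.g. {missing[0]!r}")
    per_tx = combined.groupby(ann.reindex(combined.index)).mean()
    return pd.DataFrame(
        {
            "contrast_id": meta[0]["contrast_id"],
            "transcript_id": per_tx.index,
            "bio_rep": int(meta[0]["bio_rep"]),
            "M": per_tx.to_numpy(),
        }
    )


def replicate_ratios(
    arrays: ArraySet,
    annotation: pd.DataFrame,
    span: float | None = 0.3,
    iterations: int = 3,
) -> pd.DataFrame:
    """Normalize every array and combine all dye-swap pairs.

    Returns the full ReplicateRatios table (contrast_id, transcript_id,
    bio_rep, M): one sign-corrected mean M per transcript per biological
    replicate per contrast.
    """
    normalized = {
        a: normalize_array(arrays, a, span=span, iterations=iterations)
        for a in arrays.design["array_id"]
    }
    out = []
    for (_, _), grp in arrays.design.groupby(["contrast_id", "bio_rep"]):
        ids = grp.sort_values("dye_swapped")["array_id"].tolist()
        if len(ids) != 2:
            raise StructuralError(
                f"contrast {grp['contrast_id'].iloc[0]!r} bio_rep "
                f"{grp['bio_rep'].iloc[0]}: expected 2 arrays, found {len(ids)}"
            )
        out.append(
            dye_swap_combine(
                (normalized[ids[0]], normalized[ids[1]]), arrays.design, annotation
            )
        )
    return pd.concat(out, ignore_index=True)
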