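"""Synthetic two-color experiment generator and tabular readers/writers.

The generator emulates a priming / de-priming transcriptome study: four
treatment samples (ww = water/water control, bw = BTH then water,
wf = water then flg22, bf = BTH then flg22), hybridized pairwise on
two-color arrays with dye-swapped technical replicates of each biological
replicate.  Every transcript is planted into one of seven memory classes
whose log2 effect sizes relative to ww determine the expected outcome of
the downstream contrast set-algebra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SAMPLES = ("ww", "bw", "wf", "bf")

#: contrast_id -> (reference sample, treatment sample).  The canonical
#: log2-ratio orientation is treatment over reference: M > 0 means higher
#: expression in the later-named (treated) sample.
CONTRASTS: dict[str, tuple[str, str]] = {
    "ww_wf": ("ww", "wf"),
    "ww_bw": ("ww", "bw"),
    "bw_bf": ("bw", "bf"),
    "wf_bf": ("wf", "bf"),
    "ww_bf": ("ww", "bf"),
}

MEMORY_CLASSES = (
    "null",
    "bth_only",
    "flg_only",
    "classA_concordant",
    "deprimed",
    "persistent_primed",
    "transgressive",
)

ANNOTATION_COLUMNS = ["probe_id", "transcript_id", "gene_id", "orientation"]
DESIGN_COLUMNS = [
    "array_id",
    "sample_cy3",
    "sample_cy5",
    "bio_rep",
    "dye_swapped",
    "contrast_id",
]
INTENSITY_COLUMNS = ["array_id", "probe_id", "red", "green"]
TRUTH_COLUMNS = ["transcript_id", "memory_class", "effect_bw", "effect_wf", "effect_bf"]


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class StructuralError(ValueError):
    """Input tables violate a structural invariant (missing probe, bad design row)."""


def _default_proportions() -> dict[str, float]:
    # Memory-class mass mirrors the planted-recovery study conditions: the
    # conditional Class-B composition is 0.16/0.025/0.014 -> ~80.4% de-primed,
    # 12.6% primed, 7.0% transgressive.
    return {
        "null": 0.700,
        "bth_only": 0.030,
        "flg_only": 0.030,
        "classA_concordant": 0.041,
        "deprimed": 0.160,
        "persistent_primed": 0.025,
        "transgressive": 0.014,
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic experiment.

    noise_sd_log2 is the standard deviation of a single array's log2-ratio
    (M) noise; each channel receives independent Gaussian noise of
    sd = noise_sd_log2 / sqrt(2).  dye_bias_coeffs are polynomial
    coefficients in A (constant first), attached to the red dye so the bias
    sign follows the dye, not the sample, across swaps.
    """

    n_transcripts: int = 2000
    antisense_fraction: float = 0.25
    class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    effect_size_log2: float = 1.5
    noise_sd_log2: float = 0.25
    dye_bias_coeffs: tuple[float, ...] = (1.0, -0.15, 0.005)
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    n_bio_reps: int = 2
    primed_retention: float = 0.5
    transgressive_gain: float = 2.0
    contrasts: tuple[str, ...] = tuple(CONTRASTS)
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 10:
            raise ConfigurationError(
                f"n_transcripts={self.n_transcripts} < 10: degenerate statistics"
            )
        unknown = set(self.class_proportions) - set(MEMORY_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown memory classes: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(
                f"class_proportions sum to {total!r}, not 1 within 1e-9"
            )
        if any(v < 0 for v in self.class_proportions.values()):
            raise ConfigurationError("class_proportions must be non-negative")
        if not 0.0 <= self.antisense_fraction <= 1.0:
            raise ConfigurationError("antisense_fraction must lie in [0, 1]")
        if self.noise_sd_log2 < 0 or self.baseline_log2_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.n_bio_reps < 1:
            raise ConfigurationError("n_bio_reps must be >= 1")
        bad = set(self.contrasts) - set(CONTRASTS)
        if bad:
            raise ConfigurationError(f"unknown contrasts: {sorted(bad)}")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class ArraySet:
    """Per-array two-channel intensities plus the hybridization design.

    design: one row per array (DESIGN_COLUMNS); intensities: long table,
    one row per (array_id, probe_id) with strictly positive red/green
    fluorescence values over a shared probe universe.
    """

    design: pd.DataFrame
    intensities: pd.DataFrame

    def probe_ids(self) -> pd.Index:
        return pd.Index(self.intensities["probe_id"].unique())

    def array_intensities(self, array_id: str) -> pd.DataFrame:
        sub = self.intensities[self.intensities["array_id"] == array_id]
        if sub.empty:
            raise StructuralError(f"array {array_id!r} has no intensity rows")
        return sub.reset_index(drop=True)

    def validate(self) -> None:
        validate_design(self.design)
        if (self.intensities[["red", "green"]] <= 0).any().any():
            raise StructuralError("non-positive intensity encountered")
        universe = set(self.intensities["probe_id"].unique())
        per_array = self.intensities.groupby("array_id")["probe_id"]
        for array_id, probes in per_array:
            missing = universe - set(probes)
            if missing:
                example = sorted(missing)[0]
                raise StructuralError(
                    f"array {array_id!r} is missing {len(missing)} probes "
                    f"(e.g. {example!r})"
                )


def validate_design(design: pd.DataFrame) -> None:
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise StructuralError(f"design table missing columns: {sorted(missing)}")
    same = design["sample_cy3"] == design["sample_cy5"]
    if same.any():
        bad = design.loc[same, "array_id"].iloc[0]
        raise StructuralError(f"array {bad!r}: sample_cy3 == sample_cy5")
    if design["array_id"].duplicated().any():
        raise StructuralError("duplicate array_id in design")
    for (contrast_id, bio_rep), grp in design.groupby(["contrast_id", "bio_rep"]):
        flags = sorted(grp["dye_swapped"].astype(bool).tolist())
        if flags != [False, True]:
            raise StructuralError(
                f"contrast {contrast_id!r} bio_rep {bio_rep}: expected exactly one "
                f"dye-swapped and one standard array, got flags {flags}"
            )


# ---------------------------------------------------------------------------
# simulation


def _planted_effects(
    classes: np.ndarray, signs: np.ndarray, config: SimConfig
) -> pd.DataFrame:
    """Log2 effects per treatment sample relative to ww, by memory class."""
    e = config.effect_size_log2 * signs
    bw = np.zeros(len(classes))
    wf = np.zeros(len(classes))
    bf = np.zeros(len(classes))

    def mask(name: str) -> np.ndarray:
        return classes == name

    m = mask("bth_only")  # BTH effect persists, flg22 changes nothing
    bw[m], bf[m] = e[m], e[m]
    m = mask("flg_only")  # flg22 effect regardless of prior BTH
    wf[m], bf[m] = e[m], e[m]
    m = mask("classA_concordant")  # concordant BTH/flg22 responders
    bw[m], wf[m], bf[m] = e[m], e[m], e[m]
    m = mask("deprimed")  # memorized by BTH, erased by subsequent flg22
    bw[m] = e[m]
    m = mask("persistent_primed")  # partial retention after flg22
    bw[m], bf[m] = e[m], config.primed_retention * e[m]
    m = mask("transgressive")  # amplified instead of inverted in bw->bf
    bw[m], bf[m] = e[m], config.transgressive_gain * e[m]
    return pd.DataFrame({"effect_bw": bw, "effect_wf": wf, "effect_bf": bf})


def simulate_experiment(
    config: SimConfig,
) -> tuple[ArraySet, pd.DataFrame, pd.DataFrame]:
    """Simulate a full dye-swap experiment.

    Returns (ArraySet, ProbeAnnotation table, TruthTable).  Deterministic for
    a fixed config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts

    class_names = [c for c in MEMORY_CLASSES if c in config.class_proportions]
    probs = np.array([config.class_proportions[c] for c in class_names], dtype=float)
    probs = probs / probs.sum()
    classes = rng.choice(np.array(class_names, dtype=object), size=n, p=probs)
    signs = rng.choice(np.array([-1.0, 1.0]), size=n)
    effects = _planted_effects(classes, signs, config)
    effects.loc[classes == "null", :] = 0.0

    width = max(5, len(str(n)))
    transcript_ids = np.array([f"T{i:0{width}d}" for i in range(1, n + 1)])
    antisense = rng.random(n) < config.antisense_fraction
    sense_idx = np.flatnonzero(~antisense)
    gene_ids = np.array([f"G{i:0{width}d}" for i in range(1, n + 1)], dtype=object)
    if len(sense_idx):
        # antisense transcripts share the gene of a random sense partner
        partners = rng.choice(sense_idx, size=int(antisense.sum()))
        gene_ids[antisense] = gene_ids[partners]
    annotation = pd.DataFrame(
        {
            "probe_id": np.char.add("P_", transcript_ids.astype(str)),
            "transcript_id": transcript_ids,
            "gene_id": gene_ids,
            "orientation": np.where(antisense, "antisense", "sense"),
        }
    )

    truth = pd.DataFrame({"transcript_id": transcript_ids, "memory_class": classes})
    truth = pd.concat([truth, effects], axis=1)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    abundance = {
        "ww": baseline,
        "bw": baseline + effects["effect_bw"].to_numpy(),
        "wf": baseline + effects["effect_wf"].to_numpy(),
        "bf": baseline + effects["effect_bf"].to_numpy(),
    }

    design_rows = []
    intensity_frames = []
    coeffs = np.asarray(config.dye_bias_coeffs, dtype=float)
    chan_sd = config.noise_sd_log2 / math.sqrt(2.0)
    for contrast_id in config.contrasts:
        ref, trt = CONTRASTS[contrast_id]
        for bio_rep in range(1, config.n_bio_reps + 1):
            for swapped in (False, True):
                tag = "swap" if swapped else "std"
                array_id = f"{contrast_id}_r{bio_rep}_{tag}"
                # red (cy5) carries the treatment on standard arrays
                sample_cy5, sample_cy3 = (ref, trt) if swapped else (trt, ref)
                design_rows.append(
                    {
                        "array_id": array_id,
                        "sample_cy3": sample_cy3,
                        "sample_cy5": sample_cy5,
                        "bio_rep": bio_rep,
                        "dye_swapped": swapped,
                        "contrast_id": contrast_id,
                    }
                )
                a_red = abundance[sample_cy5]
                a_green = abundance[sample_cy3]
                a_mid = 0.5 * (a_red + a_green)
                bias = np.polynomial.polynomial.polyval(a_mid, coeffs)
                log_red = a_red + 0.5 * bias + rng.normal(0.0, chan_sd, n)
                log_green = a_green - 0.5 * bias + rng.normal(0.0, chan_sd, n)
                intensity_frames.append(
                    pd.DataFrame(
                        {
                            "array_id": array_id,
                            "probe_id": annotation["probe_id"],
                            "red": np.maximum(np.exp2(log_red), 1.0),
                            "green": np.maximum(np.exp2(log_green), 1.0),
                        }
                    )
                )

    arrays = ArraySet(
        design=pd.DataFrame(design_rows, columns=DESIGN_COLUMNS),
        intensities=pd.concat(intensity_frames, ignore_index=True),
    )
    return arrays, annotation, truth


# ---------------------------------------------------------------------------
# tabular IO (tab-delimited, UTF-8, '#' comment lines allowed)


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(required) - set(df.columns)
    if missing:
        raise StructuralError(f"{path}: missing columns {sorted(missing)}")
    return df


def _write_tsv(df: pd.DataFrame, path) -> None:
    # %.17g round-trips doubles exactly through text
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_arrayset(intensity_path, design_path, offset: float = 0.0) -> ArraySet:
    """Read intensity + design TSVs into an ArraySet.

    offset: additive constant applied to both channels before the positivity
    check, for upstream tables containing background-subtracted values.
    """
    intens = _read_tsv(intensity_path, INTENSITY_COLUMNS)[INTENSITY_COLUMNS].copy()
    for col in ("red", "green"):
        # astype(float) uses exact strtod and round-trips %.17g output
        intens[col] = intens[col].astype(float) + offset
    if (intens[["red", "green"]] <= 0).any().any():
        bad = intens.loc[(intens[["red", "green"]] <= 0).any(axis=1)].iloc[0]
        raise StructuralError(
            f"non-positive intensity for probe {bad['probe_id']!r} on array "
            f"{bad['array_id']!r}; supply a positive additive offset"
        )
    design = _read_tsv(design_path, DESIGN_COLUMNS)[DESIGN_COLUMNS].copy()
    design["bio_rep"] = pd.to_numeric(design["bio_rep"], errors="raise").astype(int)
    design["dye_swapped"] = design["dye_swapped"].map(
        {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
    )
    if design["dye_swapped"].isna().any():
        raise StructuralError("dye_swapped must be boolean (True/False/1/0)")
    arrays = ArraySet(design=design, intensities=intens)
    arrays.validate()
    return arrays


def write_arrayset(arrays: ArraySet, intensity_path, design_path) -> None:
    _write_tsv(arrays.intensities[INTENSITY_COLUMNS], intensity_path)
    _write_tsv(arrays.design[DESIGN_COLUMNS], design_path)


def read_annotation(path) -> pd.DataFrame:
    ann = _read_tsv(path, ANNOTATION_COLUMNS)[ANNOTATION_COLUMNS]
    if ann["probe_id"].duplicated().any():
        raise StructuralError("duplicate probe_id in annotation")
    bad = ~ann["orientation"].isin(["sense", "antisense"])
    if bad.any():
        raise StructuralError(
            f"invalid orientation values: {sorted(ann.loc[bad, 'orientation'].unique())}"
        )
    per_tx = ann.groupby("transcript_id")["orientation"].nunique()
    if (per_tx > 1).any():
        raise StructuralError("a transcript maps to more than one orientation")
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    _write_tsv(ann[ANNOTATION_COLUMNS], path)


def read_truth(path) -> pd.DataFrame:
    truth = _read_tsv(path, TRUTH_COLUMNS)[TRUTH_COLUMNS].copy()
    for col in ("effect_bw", "effect_wf", "effect_bf"):
        truth[col] = pd.to_numeric(truth[col], errors="raise")
    return truth


def write_truth(truth: pd.DataFrame, path) -> None:
    _write_tsv(truth[TRUTH_COLUMNS], path)
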