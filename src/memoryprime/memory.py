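"""Contrast set-algebra for transcriptional memory.

Class A collects transcripts differentially expressed both by the priming
compound alone (ww vs. bw) and by the elicitor alone (ww vs. wf): common
BTH/flg22 responders, whose global trend is sign concordance.  Class B
collects transcripts differentially expressed by priming (ww vs. bw) and
again when the primed plants meet the elicitor (bw vs. bf): memorized
transcripts re-examined after the second stress, whose global trend is sign
inversion.  Class B members are then partitioned, hierarchically and
exhaustively, into

  transgressive : direction in bw_bf equals the direction in ww_bw,
                  violating the expected inversion (checked first);
  de-primed     : not significant in ww vs. bf — expression returned to the
                  pre-treatment baseline;
  primed        : still significant in ww vs. bf.

A Fisher exact test on the 2x2 table of (direction in ww_bw) x (direction
in bw_bf) quantifies the inversion pattern.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

LABELS = ("deprimed", "primed", "transgressive")

#: expected cross-contrast sign pattern per class: Class A transcripts follow
#: the two single-stress responses concordantly; Class B transcripts invert
#: between the priming response and the post-elicitor response.
EXPECTED_TREND = {"A": "concordant", "B": "inverted"}


@dataclass
class ContrastBundle:
    """Named ContrastTables (diffexpr output, indexed by transcript_id).

    `tables` must carry the full p-value table for ww_bf — not only its
    DETs — because the de-primed test needs p for every Class B transcript.
    """

    tables: dict[str, pd.DataFrame]
    alpha: float = 0.05

    def det(self, contrast_id: str) -> dict[str, str]:
        """transcript_id -> direction for transcripts with p < alpha."""
        table = self._table(contrast_id)
        de = table[table["p"] < self.alpha]
        return dict(zip(de.index, de["direction"]))

    def _table(self, contrast_id: str) -> pd.DataFrame:
        try:
            return self.tables[contrast_id]
        except KeyError:
            raise KeyError(
                f"contrast {contrast_id!r} not available; have {sorted(self.tables)}"
            ) from None


def venn_counts(sets: dict[str, set]) -> dict[frozenset, int]:
    """Exclusive region counts of a 4-set Venn diagram.

    Returns, for each of the 15 non-empty name subsets, the number of
    elements belonging to exactly those sets.  Exclusive regions sum to the
    size of the union.
    """
    names = list(sets)
    if len(names) != 4:
        raise ValueError(f"need exactly 4 named sets, got {len(names)}")
    if len(set(names)) != 4:
        raise ValueError("duplicate contrast names")
    regions = {
        frozenset(combo): 0
        for r in range(1, 5)
        for combo in combinations(names, r)
    }
    for element in set().union(*sets.values()):
        membership = frozenset(n for n in names if element in sets[n])
        regions[membership] += 1
    return regions


def class_a(bundle: ContrastBundle) -> pd.DataFrame:
    """Common DETs of ww_bw and ww_wf with concordance bookkeeping.

    Columns: dir_bw, dir_wf, subcategory (up/down_by_BTH), transgressive
    (discordant directions between the two single-stress responses).
    """
    det_bw = bundle.det("ww_bw")
    det_wf = bundle.det("ww_wf")
    common = sorted(set(det_bw) & set(det_wf))
    dir_bw = np.array([det_bw[t] for t in common], dtype=object)
    dir_wf = np.array([det_wf[t] for t in common], dtype=object)
    return pd.DataFrame(
        {
            "dir_bw": dir_bw,
            "dir_wf": dir_wf,
            "subcategory": np.where(dir_bw == "up", "up_by_BTH", "down_by_BTH"),
            "transgressive": dir_bw != dir_wf,
        },
        index=pd.Index(common, name="transcript_id"),
    )


def class_b(bundle: ContrastBundle) -> pd.DataFrame:
    """Common DETs of ww_bw and bw_bf (memorized transcripts re-tested).

    Columns: dir_bw, dir_bwbf.
    """
    det_bw = bundle.det("ww_bw")
    det_bwbf = bundle.det("bw_bf")
    common = sorted(set(det_bw) & set(det_bwbf))
    return pd.DataFrame(
        {
            "dir_bw": [det_bw[t] for t in common],
            "dir_bwbf": [det_bwbf[t] for t in common],
        },
        index=pd.Index(common, name="transcript_id"),
    )


def label_memory(
    dir_bw: np.ndarray, dir_bwbf: np.ndarray, p_wwbf: np.ndarray, alpha: float
) -> np.ndarray:
    """Vectorized hierarchical labelling rule for Class B transcripts.

    1. transgressive when bw_bf direction equals ww_bw direction (the
       expected Class B trend is inversion);
    2. otherwise de-primed when p(ww_bf) > alpha (back to baseline);
    3. otherwise primed.
    The three labels are mutually exclusive and exhaust Class B.
    """
    dir_bw = np.asarray(dir_bw, dtype=object)
    dir_bwbf = np.asarray(dir_bwbf, dtype=object)
    p_wwbf = np.asarray(p_wwbf, dtype=float)
    return np.where(
        dir_bw == dir_bwbf,
        "transgressive",
        np.where(p_wwbf > alpha, "deprimed", "primed"),
    ).astype(object)


def classify_memory(
    class_b_table: pd.DataFrame, bundle: ContrastBundle, alpha: float | None = None
) -> pd.DataFrame:
    """MemoryLabelTable for Class B: subcategory, label, per-transcript ps.

    Requires the full ww_bf ContrastTable in the bundle; a Class B
    transcript absent from it is a hard error.
    """
    alpha = bundle.alpha if alpha is None else alpha
    wwbf = bundle._table("ww_bf")
    missing = class_b_table.index.difference(wwbf.index)
    if len(missing):
        raise KeyError(
            f"Class B transcript(s) missing from the ww_bf table: "
            f"{list(missing[:5])}"
        )
    p_wwbf = wwbf.loc[class_b_table.index, "p"].to_numpy(dtype=float)
    dir_bw = class_b_table["dir_bw"].to_numpy(dtype=object)
    labels = label_memory(dir_bw, class_b_table["dir_bwbf"].to_numpy(), p_wwbf, alpha)
    return pd.DataFrame(
        {
            "subcategory": np.where(dir_bw == "up", "up_by_BTH", "down_by_BTH"),
            "label": labels,
            "transgressive": labels == "transgressive",
            "p_wwbf": p_wwbf,
        },
        index=class_b_table.index,
    )


def label_percentages(label_table: pd.DataFrame) -> dict[str, float]:
    """Percentage of each memory label over Class B (sums to 100)."""
    n = len(label_table)
    if n == 0:
        return {label: float("nan") for label in LABELS}
    counts = label_table["label"].value_counts()
    return {label: float(100.0 * counts.get(label, 0) / n) for label in LABELS}


def orientation_breakdown(
    table: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Sense/antisense x transgressive percentage table per subcategory.

    `table` needs columns subcategory and transgressive (Class A output or a
    MemoryLabelTable).  Every transcript must be annotated.  Each row gives
    the percentage of {non-transgressive sense/antisense, transgressive
    sense/antisense} within that subcategory, summing to 100.
    """
    orientation = annotation.drop_duplicates("transcript_id").set_index(
        "transcript_id"
    )["orientation"]
    missing = table.index.difference(orientation.index)
    if len(missing):
        raise KeyError(f"unannotated transcript(s): {list(missing[:5])}")
    ori = orientation.loc[table.index]
    cols = [
        "nontransgressive_sense",
        "nontransgressive_antisense",
        "transgressive_sense",
        "transgressive_antisense",
    ]
    rows = {}
    for subcat, grp in table.groupby("subcategory"):
        n = len(grp)
        o = ori.loc[grp.index].to_numpy()
        tg = grp["transgressive"].to_numpy(dtype=bool)
        rows[subcat] = [
            100.0 * np.sum(~tg & (o == "sense")) / n,
            100.0 * np.sum(~tg & (o == "antisense")) / n,
            100.0 * np.sum(tg & (o == "sense")) / n,
            100.0 * np.sum(tg & (o == "antisense")) / n,
        ]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    out.index.name = "subcategory"
    return out


def _hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """P[X = k] for X ~ Hypergeometric(N, K, n), from log-factorials."""

    def lchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return np.exp(lchoose(K, k) + lchoose(N - K, n - k) - lchoose(N, n))


def fisher_exact_2x2(
    table: np.ndarray, two_sided_rule: str = "minlike"
) -> tuple[float, float]:
    """Two-sided Fisher exact test built on the hypergeometric pmf.

    Conditioning on the margins, the (0,0) cell follows a hypergeometric
    law; the two-sided p sums the probabilities of all tables with the same
    margins whose probability does not exceed the observed one ("minlike",
    the common convention).  two_sided_rule="double" instead doubles the
    smaller one-sided tail (capped at 1).  Returns (odds_ratio, p).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.float64(a * d) / np.float64(b * c) if b * c else np.inf
    if a * d == 0 and b * c == 0:
        odds = np.nan
    if min(row1, col1, n_total - row1, n_total - col1) == 0:
        warnings.warn("zero margin in 2x2 table; p = 1", stacklevel=2)
        return float(odds), 1.0

    support = np.arange(max(0, col1 - (n_total - row1)), min(row1, col1) + 1)
    pmf = _hypergeom_pmf(support, n_total, row1, col1)
    p_obs = pmf[a - support[0]]
    if two_sided_rule == "minlike":
        # relative tolerance guards ties against floating-point noise
        p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    elif two_sided_rule == "double":
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown two-sided rule {two_sided_rule!r}")
    return float(odds), min(p, 1.0)


def inversion_fisher_test(
    class_b_table: pd.DataFrame, two_sided_rule: str = "minlike"
) -> tuple[np.ndarray, float, float]:
    """Association between priming direction and post-elicitor direction.

    Builds the 2x2 table rows = direction in ww_bw (up/down), columns =
    direction in bw_bf (up/down) over Class B, and returns
    (table, odds_ratio, two-sided p).  A strong inversion pattern loads the
    off-diagonal cells and yields a small p with odds ratio < 1.
    """
    if len(class_b_table) < 1:
        raise ValueError("Class B is empty; nothing to test")
    up_bw = class_b_table["dir_bw"].to_numpy(dtype=object) == "up"
    up_bf = class_b_table["dir_bwbf"].to_numpy(dtype=object) == "up"
    table = np.array(
        [
            [int(np.sum(up_bw & up_bf)), int(np.sum(up_bw & ~up_bf))],
            [int(np.sum(~up_bw & up_bf)), int(np.sum(~up_bw & ~up_bf))],
        ]
    )
    odds, p = fisher_exact_2x2(table, two_sided_rule=two_sided_rule)
    return table, odds, p
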