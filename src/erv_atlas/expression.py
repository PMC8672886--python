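"""Expression-matrix integration for annotated elements.

Normalisation (TPM/FPKM), expression-threshold filtering (TPM > 100 for
stage panels, FPKM > 1 for tissue panels), per-condition specificity and
overlap (Venn-style) summaries, virus-responsiveness calling by an
explicit fold-change rule, and positional (cis, <=10 kb) plus
correlational (trans, |R| > 0.85, p < 0.01) element-gene association.

Replicates are aggregated by mean before thresholding. Correlation
p-values come from the two-sided t-test on Pearson's R; raw p-values
drive the calls, with a Benjamini-Hochberg column emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AssociationHit:
    element_id: str
    gene_id: str
    mode: str                   # cis | trans
    R: float = float("nan")
    p: float = float("nan")
    distance: int | None = None  # cis only


def normalize_counts(
    counts: pd.DataFrame, lengths: pd.Series | dict, mode: str = "TPM"
) -> pd.DataFrame:
    """TPM or FPKM normalisation of a features x samples count matrix.

    FPKM_i = count_i * 1e9 / (length_i * library_size);
    TPM_i = rate_i * 1e6 / sum(rates), rate_i = count_i / length_i.
    TPM columns sum to 1e6 by construction.
    """
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise KeyError(f"missing feature lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be > 0")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    if mode == "FPKM":
        return counts.mul(1e9).div(lengths, axis=0).div(lib, axis=1)
    if mode == "TPM":
        rates = counts.div(lengths, axis=0)
        return rates.div(rates.sum(axis=0), axis=1).mul(1e6)
    raise ValueError(f"unknown mode {mode!r}")


def condition_means(matrix: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Mean over replicates, one column per condition."""
    cond = sample_sheet.set_index("sample")["condition"]
    unknown = [s for s in matrix.columns if s not in cond.index]
    if unknown:
        raise KeyError(f"samples missing from sheet: {unknown[:5]}")
    return matrix.T.groupby(cond.loc[matrix.columns].to_numpy()).mean().T


def expressed_set(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    threshold: float,
    min_conditions: int = 1,
) -> dict[str, set[str]]:
    """Features exceeding ``threshold`` (replicate mean) per condition.

    Features passing in fewer than ``min_conditions`` conditions are
    dropped from every set.
    """
    means = condition_means(matrix, sample_sheet)
    sets = {c: set(means.index[means[c] > threshold]) for c in means.columns}
    if min_conditions > 1:
        tally = pd.Series(0, index=means.index)
        for s in sets.values():
            tally[list(s)] += 1
        keep = set(tally.index[tally >= min_conditions])
        sets = {c: s & keep for c, s in sets.items()}
    return sets


def specificity_and_overlap(sets: dict[str, set[str]]):
    """Condition-specific features plus the full overlap table.

    specific(c) = set(c) minus the union of all other sets. The overlap
    table lists, for every combination of conditions, the number of
    features expressed in exactly that combination (Venn regions).
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 conditions")
    conds = list(sets)
    specific = {
        c: sets[c] - set().union(*(sets[o] for o in conds if o != c)) for c in conds
    }
    regions = []
    for k in range(1, len(conds) + 1):
        for combo in combinations(conds, k):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[c] for c in conds if c not in combo), set())
            regions.append(
                {"conditions": "+".join(combo), "exact_count": len(inside - outside),
                 "intersection_count": len(inside)}
            )
    return specific, pd.DataFrame(regions)


def virus_responsive(
    control: pd.DataFrame,
    infected: pd.DataFrame,
    min_expr: float = 1.0,
    min_log2fc: float = 1.0,
    pseudocount: float = 1.0,
) -> set[str]:
    """Upregulated features under infection, by explicit threshold rule.

    A feature is flagged iff its infected replicate mean exceeds
    ``min_expr`` and log2((infected+pc)/(control+pc)) >= ``min_log2fc``.
    """
    if control.shape[1] == 0 or infected.shape[1] == 0:
        raise ValueError("empty condition")
    common = control.index.intersection(infected.index)
    c = control.loc[common].mean(axis=1)
    i = infected.loc[common].mean(axis=1)
    lfc = np.log2((i + pseudocount) / (c + pseudocount))
    return set(common[(i > min_expr) & (lfc >= min_log2fc)])


def cis_neighbors(
    elements: dict[str, tuple[str, int, int]],
    genes: dict[str, tuple[str, int, int]],
    window: int = 10_000,
) -> list[AssociationHit]:
    """Element-gene pairs within ``window`` bp on the same chromosome.

    Intervals are (chrom, start, end), 0-based half-open; overlapping
    intervals have distance 0, otherwise distance is the gap between the
    nearest interval ends.
    """
    hits = []
    for eid, (ec, es, ee) in elements.items():
        for gid, (gc_, gs, ge) in genes.items():
            if ec != gc_:
                continue
            gap = max(gs - ee, es - ge, 0)
            if gap <= window:
                hits.append(AssociationHit(eid, gid, "cis", distance=int(gap)))
    hits.sort(key=lambda h: (h.element_id, h.gene_id))
    return hits


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided t-test p-value for a Pearson correlation at sample size n."""
    if n < 3:
        raise ValueError("need at least 3 samples")
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def trans_partners(
    erv_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    r_min: float = 0.85,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """All element-gene pairs with |Pearson R| > r_min and p < p_max.

    Expression frames share sample columns; zero-variance features are
    skipped. Returns a tidy frame with R, raw p and a Benjamini-Hochberg
    adjusted p for every *tested* pair, plus the ``trans`` call flag.
    """
    samples = erv_expr.columns.intersection(gene_expr.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples")
    E = erv_expr[samples].to_numpy(float)
    G = gene_expr[samples].to_numpy(float)
    n = len(samples)
    e_sd = E.std(axis=1)
    g_sd = G.std(axis=1)
    e_ok = np.flatnonzero(e_sd > 0)
    g_ok = np.flatnonzero(g_sd > 0)
    Ez = (E[e_ok] - E[e_ok].mean(axis=1, keepdims=True)) / e_sd[e_ok, None]
    Gz = (G[g_ok] - G[g_ok].mean(axis=1, keepdims=True)) / g_sd[g_ok, None]
    R = Ez @ Gz.T / n
    rows = []
    for ii, ei in enumerate(e_ok):
        for jj, gi in enumerate(g_ok):
            r = float(np.clip(R[ii, jj], -1.0, 1.0))
            rows.append(
                {
                    "element_id": erv_expr.index[ei],
                    "gene_id": gene_expr.index[gi],
                    "R": r,
                    "p": correlation_pvalue(r, n),
                }
            )
    df = pd.DataFrame(rows, columns=["element_id", "gene_id", "R", "p"])
    if len(df):
        m = len(df)
        idx = np.argsort(df["p"].to_numpy(), kind="stable")
        bh_sorted = df["p"].to_numpy()[idx] * m / np.arange(1, m + 1)
        bh_sorted = np.minimum.accumulate(bh_sorted[::-1])[::-1]
        bh = np.empty(m)
        bh[idx] = np.minimum(bh_sorted, 1.0)
        df["p_bh"] = bh
        df["trans"] = (df["R"].abs() > r_min) & (df["p"] < p_max)
    else:
        df["p_bh"] = []
        df["trans"] = []
    return df
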