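"""Chromosomal distribution statistics for annotated elements.

Per-chromosome densities, expected counts under a uniform genome-wide
density, a two-cell chi-square enrichment test (on-chromosome vs
off-chromosome, 1 df), Pearson correlations of counts with chromosome
length and GC content, and windowed density tracks.

A packaged reference table (25 zebrafish chromosomes with published
counts, expected counts and densities) ships as a TSV fixture for
regression tests: :func:`load_reference_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ChromStats:
    chrom: str
    length_mb: float
    gc_percent: float
    detected: int
    expected: float
    density: float
    chi2: float
    p: float
    direction: str  # enriched | depleted | none


def load_reference_table() -> pd.DataFrame:
    """The packaged per-chromosome reference table (zebrafish, 25 rows)."""
    with resources.files("erv_atlas.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def chromosome_density(detected, lengths_mb):
    """Elements per Mb, elementwise; full precision (round only for display)."""
    detected = np.asarray(detected, dtype=float)
    lengths = np.asarray(lengths_mb, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be > 0")
    return detected / lengths


def expected_counts(lengths_mb, genomewide_density: float):
    """Expected count per chromosome: length x genome-wide density."""
    if genomewide_density < 0:
        raise ValueError("density must be >= 0")
    return np.asarray(lengths_mb, dtype=float) * genomewide_density


def chisq_enrichment(
    observed: float, expected: float, total: float, alpha: float = 0.01
) -> tuple[float, float, str]:
    """Two-cell goodness-of-fit test for one chromosome.

    Cells are (on-chromosome, off-chromosome) with expectations
    (E, T - E):  chi2 = (O-E)^2/E + ((T-O)-(T-E))^2/(T-E), 1 df.
    Direction is 'enriched' iff O > E at p < alpha, 'depleted' iff O < E
    at p < alpha, else 'none'.
    """
    if expected <= 0 or expected >= total:
        raise ValueError("need 0 < expected < total")
    if observed > total:
        raise ValueError("observed cannot exceed total")
    off_o = total - observed
    off_e = total - expected
    chi2 = (observed - expected) ** 2 / expected + (off_o - off_e) ** 2 / off_e
    p = float(stats.chi2.sf(chi2, df=1))
    if p < alpha:
        direction = "enriched" if observed > expected else "depleted"
    else:
        direction = "none"
    return float(chi2), p, direction


def count_length_gc_correlation(table: pd.DataFrame) -> dict:
    """Pearson correlations of detected counts with length and GC.

    Expects columns ``detected``, ``length_mb``, ``gc_percent``; returns
    {"length": (R, p), "gc": (R, p)} using the two-sided t-test on R.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 chromosomes")
    out = {}
    for key, col in (("length", "length_mb"), ("gc", "gc_percent")):
        x = table["detected"].to_numpy(float)
        y = table[col].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"zero variance in {col}")
        r, p = stats.pearsonr(x, y)
        out[key] = (float(r), float(p))
    return out


def chromosome_table(
    counts: dict[str, int],
    lengths_mb: dict[str, float],
    gc_percent: dict[str, float] | None = None,
    genomewide_density: float | None = None,
    total: int | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Assemble the full per-chromosome statistics table.

    ``genomewide_density`` defaults to total/sum(lengths) (it is kept
    configurable because a published density may rest on a genome length
    that includes unplaced scaffolds); ``total`` defaults to the sum of
    counts. A Bonferroni-adjusted p column is emitted alongside the raw p.
    """
    chroms = sorted(lengths_mb, key=lambda c: (len(c), c))
    det = np.array([counts.get(c, 0) for c in chroms], dtype=float)
    lens = np.array([lengths_mb[c] for c in chroms], dtype=float)
    if total is None:
        total = int(det.sum())
    if genomewide_density is None:
        genomewide_density = total / lens.sum()
    dens = chromosome_density(det, lens)
    exp = expected_counts(lens, genomewide_density)
    rows = []
    for c, o, l, e, d in zip(chroms, det, lens, exp, dens):
        if 0 < e < total and o <= total:
            chi2, p, direction = chisq_enrichment(o, e, total, alpha=alpha)
        else:  # degenerate (e.g. single chromosome): test undefined
            chi2, p, direction = np.nan, np.nan, "none"
        rows.append(
            {
                "chrom": c,
                "length_mb": l,
                "gc_percent": (gc_percent or {}).get(c, np.nan),
                "detected": int(o),
                "expected": e,
                "density": d,
                "chi2": chi2,
                "p": p,
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
    return df


def windowed_feature_density(
    features, chrom_length: int, window: int
) -> np.ndarray:
    """Per-window feature counts along one chromosome.

    ``features`` is an iterable of (start, end) 0-based half-open
    intervals; a feature is counted in every window it overlaps, so the
    track sum can exceed the feature count. Track length is
    ceil(chrom_length / window).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    n = -(-chrom_length // window)
    track = np.zeros(n, dtype=int)
    for start, end in features:
        w0 = max(0, start // window)
        w1 = min(n - 1, (max(end - 1, start)) // window)
        track[w0 : w1 + 1] += 1
    return track
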