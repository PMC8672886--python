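"""Synthetic genomes with planted LTR retroelements and matched expression data.

Every downstream stage of the package (detection, classification, dating,
distribution statistics, protein annotation, expression integration) is
benchmarked against genomes produced here, because each planted element
carries a full ground-truth record: its age, structure, class, motif
payload and exact post-insertion coordinates.

The mutational model is deliberately minimal: after insertion the two
initially identical LTRs accumulate substitutions independently, each site
mutating with probability ``rate * age`` (uniform replacement among the
other three bases, Jukes–Cantor style). Indels are off by default, so the
divergence between the LTR pair is estimable both as a p-distance and
under the JC correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

NUCLEOTIDES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default neutral substitution rate for fish genomes, subs/site/year.
DEFAULT_RATE = 1.46e-8

#: Retroviral / retroelement classes recognised by the simulator.
CLASS_LABELS = ("Gypsy", "Bel", "Copia", "classI", "classII", "classIII")

GENE_ORDER = ("gag", "pol", "env")

# Canonical peptides for plantable motifs. The ISD 17-mers are synthetic
# stand-ins (real group consensi are not public as text); position 14
# carries the on/off residue: Q = immunosuppressive, R/K = not.
MOTIF_PEPTIDES = {
    "furin": "RSKR",
    "isd_q": "LQNRRGLDLLFLKQGGL",
    "isd_r": "LQNRRGLDLLFLKRGGL",
    "isd_k": "LQNRRGLDLLFLKKGGL",
    "cxxc": "CWLC",
    "cx5cc": "CGFEGTCC",
    "cx6cc": "CGFEGTACC",
    "cx7cc": "CGFEGTAWCC",
    "tm": "AILIIVILVIGLLFILAIVGGIVLL",
    "zf_cchc": "CFNCGKEGHIARNCRA",
}

#: Which gene ORF hosts each motif.
MOTIF_GENE = {
    "furin": "env",
    "isd_q": "env",
    "isd_r": "env",
    "isd_k": "env",
    "cxxc": "env",
    "cx5cc": "env",
    "cx6cc": "env",
    "cx7cc": "env",
    "tm": "env",
    "zf_cchc": "gag",
}

# Relative position (fraction of protein length) at which each motif is
# planted; chosen so the canonical Env architecture furin < ISD <
# C-Xn-CC < TM holds by construction.
_MOTIF_REL_POS = {
    "cxxc": 0.15,
    "furin": 0.30,
    "isd_q": 0.45,
    "isd_r": 0.45,
    "isd_k": 0.45,
    "cx5cc": 0.62,
    "cx6cc": 0.62,
    "cx7cc": 0.62,
    "zf_cchc": 0.40,
}

_CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
_STOP = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [c for c in _CODONS if c not in _STOP]

_CODON_TABLE: dict[str, list[str]] = {}
for _c in _SENSE_CODONS:
    from Bio.Seq import Seq as _Seq

    _aa = str(_Seq(_c).translate())
    _CODON_TABLE.setdefault(_aa, []).append(_c)


@dataclass(frozen=True)
class ElementSpec:
    """Blueprint for one planted provirus."""

    structure_category: str = "LTR-gag-pol-env-LTR"
    age_mya: float = 0.5
    ltr_length: int = 500
    internal_length: int = 5000
    class_label: str = "Gypsy"
    motif_payload: tuple[str, ...] = ()
    strand: str = "+"
    tsd_length: int = 4

    def __post_init__(self):
        if self.ltr_length < 1:
            raise ValueError("ltr_length must be >= 1")
        if self.age_mya < 0:
            raise ValueError("age_mya must be >= 0")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        parse_structure(self.structure_category)  # validates token
        for m in self.motif_payload:
            if m not in MOTIF_PEPTIDES:
                raise ValueError(f"unknown motif id {m!r}")


@dataclass
class TruthRecord:
    """Ground truth for one planted element (coordinates 0-based half-open)."""

    element_id: str
    chrom: str | None
    start: int
    end: int
    strand: str
    spec: ElementSpec
    expected_divergence: float
    planted_motif_coords: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    # extra bookkeeping used by benchmarks
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None
    genes: dict[str, tuple[int, int]] = field(default_factory=dict)

    def shifted(self, chrom: str, offset: int) -> "TruthRecord":
        sh = lambda iv: (iv[0] + offset, iv[1] + offset) if iv is not None else None
        return replace(
            self,
            chrom=chrom,
            start=self.start + offset,
            end=self.end + offset,
            ltr5=sh(self.ltr5),
            ltr3=sh(self.ltr3),
            genes={g: sh(iv) for g, iv in self.genes.items()},
        )


def parse_structure(token: str) -> tuple[bool, bool, bool, bool, list[str]]:
    """Split a structure token into (ltr5, solo5, ltr3, solo3, genes).

    ``LTR`` marks a full LTR, ``(LTR)`` a single LTR present at only one
    end; gene tokens must appear in gag < pol < env order.
    """
    parts = token.split("-")
    ltr5 = solo5 = ltr3 = solo3 = False
    if parts and parts[0] in ("LTR", "(LTR)"):
        ltr5, solo5 = True, parts[0] == "(LTR)"
        parts = parts[1:]
    if parts and parts[-1] in ("LTR", "(LTR)"):
        ltr3, solo3 = True, parts[-1] == "(LTR)"
        parts = parts[:-1]
    genes = list(parts)
    order = [g for g in GENE_ORDER if g in genes]
    if genes != order or len(set(genes)) != len(genes):
        raise ValueError(f"invalid structure token {token!r}")
    if not (ltr5 or ltr3 or genes):
        raise ValueError("structure token has no parts")
    if solo5 and ltr3 and not solo3:
        raise ValueError("(LTR) cannot pair with a full LTR on the other end")
    return ltr5, solo5, ltr3, solo3, genes


def generate_background(length: int, gc_fraction: float, seed) -> str:
    """I.i.d. background sequence with the requested expected GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return NUCLEOTIDES[idx].tobytes().decode()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return NUCLEOTIDES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate(seq: str, per_site_prob: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with the given probability.

    Replacement is uniform over the other three bases; probabilities are
    capped at 0.75 (the saturation point of the uniform model).
    """
    p = min(per_site_prob, 0.75)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < p
    n = int(hit.sum())
    if n:
        shifts = rng.integers(1, 4, size=n)
        codes = np.searchsorted(NUCLEOTIDES, arr[hit])
        arr[hit] = NUCLEOTIDES[(codes + shifts) % 4]
    return arr.tobytes().decode()


def _reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    return "".join(_CODON_TABLE[aa][rng.integers(0, len(_CODON_TABLE[aa]))] for aa in peptide)


def _reference_rt_panel_seqs(n_codons: int = 180) -> dict[str, str]:
    """Deterministic synthetic RT reference panel, one sequence per class.

    Stand-ins for the real curated reverse-transcriptase references (which
    cannot be shipped); generated from a fixed seed so simulator and
    classifier always agree.
    """
    panel = {}
    for i, label in enumerate(CLASS_LABELS):
        rng = np.random.default_rng(987_000 + i)
        panel[label] = "".join(
            _SENSE_CODONS[j] for j in rng.integers(0, len(_SENSE_CODONS), size=n_codons)
        )
    return panel


REFERENCE_RT_PANEL = _reference_rt_panel_seqs()

# Gene length weights used to apportion the internal region.
_GENE_WEIGHTS = {"gag": 1.0, "pol": 2.0, "env": 1.3}
_SPACER = 60  # non-coding bp between internal parts


def _build_orf(
    gene: str,
    aa_len: int,
    motifs: list[str],
    class_label: str,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[str, tuple[int, int]]]]:
    """One ORF: ATG + aa_len sense codons + stop, with motifs planted in-frame.

    Returns the nucleotide sequence and (motif_id, protein interval) pairs;
    protein coordinate 0 is the residue after the initiator Met.
    """
    codons = [_SENSE_CODONS[j] for j in rng.integers(0, len(_SENSE_CODONS), size=aa_len)]
    placements = []
    taken: list[tuple[int, int]] = []
    for m in sorted(motifs, key=lambda m: _MOTIF_REL_POS.get(m, 0.5)):
        pep = MOTIF_PEPTIDES[m]
        if m == "tm":
            pos = aa_len - len(pep) - 5
        else:
            pos = int(_MOTIF_REL_POS.get(m, 0.5) * aa_len)
        pos = max(0, min(pos, aa_len - len(pep)))
        while any(pos < e and pos + len(pep) > s for s, e in taken):
            pos += 1
        taken.append((pos, pos + len(pep)))
        pep_nt = _reverse_translate(pep, rng)
        for k in range(len(pep)):
            codons[pos + k] = pep_nt[3 * k : 3 * k + 3]
        placements.append((m, (pos, pos + len(pep))))
    if gene == "pol":
        # embed the class RT reference in-frame mid-gene
        rt = REFERENCE_RT_PANEL[class_label]
        n_rt = len(rt) // 3
        pos = max(0, (aa_len - n_rt) // 2)
        for k in range(min(n_rt, aa_len - pos)):
            codons[pos + k] = rt[3 * k : 3 * k + 3]
    return "ATG" + "".join(codons) + "TAA", placements


def synthesize_element(
    spec: ElementSpec, rate: float = DEFAULT_RATE, seed=0
) -> tuple[str, TruthRecord]:
    """Build one element sequence plus its truth record.

    Layout: TSD + 5'LTR + internal (genes with spacers) + 3'LTR + TSD.
    Both LTRs descend from one ancestor, each mutated independently at
    ``rate * age``; the expected pairwise divergence is ``2 * rate * age``.
    Coordinates in the returned record are element-relative (offset later
    by :func:`plant_elements`).
    """
    rng = np.random.default_rng(seed)
    ltr5_has, _, ltr3_has, _, genes = parse_structure(spec.structure_category)

    ancestor = _random_seq(rng, spec.ltr_length)
    per_site = rate * spec.age_mya * 1e6
    ltr5_seq = mutate(ancestor, per_site, rng) if ltr5_has else ""
    ltr3_seq = mutate(ancestor, per_site, rng) if ltr3_has else ""

    # apportion the internal region among genes (spacers between parts)
    gene_nt: dict[str, str] = {}
    placements: dict[str, list[tuple[str, tuple[int, int]]]] = {}
    if genes:
        budget = spec.internal_length - _SPACER * (len(genes) + 1)
        total_w = sum(_GENE_WEIGHTS[g] for g in genes)
        for g in genes:
            aa_len = max(100, int(budget * _GENE_WEIGHTS[g] / total_w) // 3 - 2)
            motifs = [m for m in spec.motif_payload if MOTIF_GENE[m] == g]
            gene_nt[g], placements[g] = _build_orf(g, aa_len, motifs, spec.class_label, rng)

    parts: list[tuple[str, str]] = []  # (label, seq)
    if ltr5_has:
        parts.append(("ltr5", ltr5_seq))
    for g in genes:
        parts.append(("spacer", _random_seq(rng, _SPACER)))
        parts.append((g, gene_nt[g]))
    if genes:
        parts.append(("spacer", _random_seq(rng, _SPACER)))
    elif ltr5_has and ltr3_has:
        parts.append(("spacer", _random_seq(rng, max(spec.internal_length, 1))))
    if ltr3_has:
        parts.append(("ltr3", ltr3_seq))

    tsd = _random_seq(rng, spec.tsd_length)
    body = "".join(s for _, s in parts)
    seq = tsd + body + tsd

    coords: dict[str, tuple[int, int]] = {}
    pos = len(tsd)
    for label, s in parts:
        if label != "spacer":
            coords[label] = (pos, pos + len(s))
        pos += len(s)

    motif_coords = [pl for g in genes for pl in placements.get(g, [])]
    if spec.strand == "-":
        comp = bytes.maketrans(b"ACGT", b"TGCA")
        seq = seq.encode().translate(comp)[::-1].decode()
        flip = lambda iv: (len(seq) - iv[1], len(seq) - iv[0])
        new = {}
        if "ltr5" in coords:
            new["ltr3"] = flip(coords["ltr5"])
        if "ltr3" in coords:
            new["ltr5"] = flip(coords["ltr3"])
        for g in genes:
            new[g] = flip(coords[g])
        coords = new

    truth = TruthRecord(
        element_id="",
        chrom=None,
        start=0,
        end=len(seq),
        strand=spec.strand,
        spec=spec,
        expected_divergence=2.0 * rate * spec.age_mya * 1e6,
        planted_motif_coords=motif_coords,
        ltr5=coords.get("ltr5"),
        ltr3=coords.get("ltr3"),
        genes={g: coords[g] for g in genes if g in coords},
    )
    return seq, truth


def plant_elements(
    genome: dict[str, str],
    specs: list[ElementSpec],
    min_gap: int = 2000,
    seed=0,
    rate: float = DEFAULT_RATE,
    max_tries: int = 1000,
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Insert elements at non-overlapping positions, returning exact coordinates.

    Insertion points are drawn uniformly per chromosome and rejection-sampled
    so planted elements stay at least ``min_gap`` apart; specs are processed
    in order, which makes placement deterministic under a fixed seed.
    """
    if not specs:
        return dict(genome), []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(specs) + 1)
    rng = np.random.default_rng(child_seeds[0])
    chroms = sorted(genome)

    synthesized = [
        synthesize_element(sp, rate=rate, seed=child_seeds[i + 1])
        for i, sp in enumerate(specs)
    ]
    if sum(len(s) for s, _ in synthesized) >= sum(len(v) for v in genome.values()):
        raise ValueError("total planted length exceeds genome length")

    # choose insertion points in *original* coordinates
    chosen: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}  # (pos, idx)
    unplaced = []
    for i, (seq, _) in enumerate(synthesized):
        placed = False
        for _try in range(max_tries):
            c = chroms[rng.integers(0, len(chroms))]
            pos = int(rng.integers(0, len(genome[c]) + 1))
            if all(abs(pos - p) >= min_gap for p, _ in chosen[c]):
                chosen[c].append((pos, i))
                placed = True
                break
        if not placed:
            unplaced.append(i)
    if unplaced:
        raise ValueError(f"could not place specs without overlap: {unplaced}")

    out_genome: dict[str, str] = {}
    truth: list[TruthRecord] = []
    for c in chroms:
        pieces = []
        cursor = 0
        offset = 0
        for pos, i in sorted(chosen[c]):
            seq, rec = synthesized[i]
            pieces.append(genome[c][cursor:pos])
            rec = rec.shifted(c, pos + offset)
            rec.element_id = f"sim{i:04d}"
            truth.append(rec)
            pieces.append(seq)
            offset += len(seq)
            cursor = pos
        pieces.append(genome[c][cursor:])
        out_genome[c] = "".join(pieces)
    truth.sort(key=lambda r: (r.chrom, r.start))
    return out_genome, truth


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDesign:
    """Stated experimental structure for the expression simulator.

    conditions: ordered labels (developmental stages, tissues, or
    ctrl/infected); specificity_map assigns features high expression in
    the listed condition(s) only; response_map holds log2 fold changes of
    the infected condition over its control; trans/cis pairs plant a
    target Pearson correlation between an element and a gene across all
    samples.
    """

    conditions: tuple[str, ...]
    replicates: int = 3
    specificity_map: dict[str, tuple[str, ...]] = field(default_factory=dict)
    response_map: dict[str, float] = field(default_factory=dict)
    infected_condition: str | None = None
    control_condition: str | None = None
    trans_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    cis_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    noise_sigma: float = 0.2
    baseline_mean: float = 5.0
    specific_mean: float = 4000.0
    corr_base_mean: float = 1000.0
    corr_amplitude: float = 1.0
    n_background: int = 50
    background_mean: float = 20000.0
    library_sizes: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        for _, _, r in self.trans_pairs + self.cis_pairs:
            if not -1.0 <= r <= 1.0:
                raise ValueError("target correlations must lie in [-1, 1]")
        if self.library_sizes is not None and any(
            v <= 0 for v in self.library_sizes.values()
        ):
            raise ValueError("library sizes must be > 0")


def simulate_expression(
    element_ids: list[str],
    gene_ids: list[str],
    lengths: dict[str, int],
    design: ExpressionDesign,
):
    """Counts matrix (features x samples) realising the planted design.

    Means are built multiplicatively (baseline x specificity x response x
    correlation factor), jittered log-normally with ``noise_sigma`` and
    Poisson-sampled; with ``noise_sigma == 0`` the exact expected counts
    are returned so planted fold changes are recovered identically.
    ``n_background`` strongly expressed housekeeping-like features
    (ids ``bg####``, length 1 kb) absorb library mass so that baseline
    features sit far below the TPM/FPKM panels' thresholds; features in
    a correlation pair start from ``corr_base_mean`` so Poisson noise
    cannot swamp the planted correlation. Returns
    ``(counts DataFrame, sample sheet DataFrame, feature lengths Series)``.
    """
    import pandas as pd

    for f in list(design.specificity_map) + list(design.response_map):
        if f not in element_ids and f not in gene_ids:
            raise KeyError(f"feature {f!r} in design but not in truth/annotation")
    for cs in design.specificity_map.values():
        for c in cs:
            if c not in design.conditions:
                raise KeyError(f"condition {c!r} not in design.conditions")

    rng = np.random.default_rng(design.seed)
    background = [f"bg{i:04d}" for i in range(design.n_background)]
    features = (
        list(element_ids)
        + [g for g in gene_ids if g not in element_ids]
        + background
    )
    samples = [
        (f"{c}_r{i+1}", c) for c in design.conditions for i in range(design.replicates)
    ]
    sheet = pd.DataFrame(
        {
            "sample": [s for s, _ in samples],
            "condition": [c for _, c in samples],
            "replicate": [i + 1 for _ in design.conditions for i in range(design.replicates)],
        }
    )
    n = len(samples)

    # latent per-sample factors for planted correlations
    latents = {}
    corr_term = {f: np.zeros(n) for f in features}
    for el, gene, r in design.trans_pairs + design.cis_pairs:
        z = latents.setdefault(el, rng.standard_normal(n))
        w = rng.standard_normal(n)
        corr_term[el] = design.corr_amplitude * z
        corr_term[gene] = design.corr_amplitude * (r * z + np.sqrt(max(0.0, 1 - r * r)) * w)

    lib = np.array(
        [
            (design.library_sizes or {}).get(s, 1.0)
            for s, _ in samples
        ]
    )

    corr_features = {x for el, gene, _ in design.trans_pairs + design.cis_pairs
                     for x in (el, gene)}

    mat = np.zeros((len(features), n))
    for fi, f in enumerate(features):
        if f in background:
            base = np.full(n, design.background_mean)
        elif f in corr_features and f not in design.specificity_map:
            base = np.full(n, design.corr_base_mean)
        else:
            base = np.full(n, design.baseline_mean)
        spec_conds = design.specificity_map.get(f)
        if spec_conds:
            on = np.array([c in spec_conds for _, c in samples])
            base = np.where(on, design.specific_mean, design.baseline_mean)
        if f in design.response_map and design.infected_condition:
            inf = np.array([c == design.infected_condition for _, c in samples])
            base = base * np.where(inf, 2.0 ** design.response_map[f], 1.0)
        mean = base * 2.0 ** corr_term[f] * lib
        if design.noise_sigma == 0:
            mat[fi] = mean
        else:
            jitter = rng.lognormal(mean=0.0, sigma=design.noise_sigma, size=n)
            mat[fi] = rng.poisson(mean * jitter)

    counts = pd.DataFrame(mat, index=features, columns=[s for s, _ in samples])
    out_lengths = pd.Series(
        {f: lengths.get(f, 1000) for f in features}, name="length"
    )
    return counts, sheet, out_lengths
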