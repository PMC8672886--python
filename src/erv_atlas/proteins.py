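"""ORF discovery and the retroviral Gag/Env motif grammar.

Implements the protein-level feature set used to characterise envelope
(and capsid) ORFs of endogenous retroviruses:

* furin cleavage site, consensus R/K-X-R/K-R (separates the SU and TM
  subunits of Env);
* the 17-aa immunosuppressive domain (ISD), located by profile match;
  residue 14 switches immunosuppressive activity: Q = "on", R/K = "off";
* C-X-X-C motif (SU-TM interaction) and the C-X{5,6,7}-CC motifs that
  follow the ISD;
* a C-terminal transmembrane segment from Kyte–Doolittle hydropathy.

A valid Env architecture presents these features in the order
furin < ISD < C-Xn-CC < TM.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_X = f"[{AA20}]"  # wildcard: any standard residue; X never matches

MOTIF_PATTERNS = {
    "furin": f"[RK]{_X}[RK]R",
    "cxxc": f"C{_X}{{2}}C",
    "cx5cc": f"C{_X}{{5}}CC",
    "cx6cc": f"C{_X}{{6}}CC",
    "cx7cc": f"C{_X}{{7}}CC",
}

_COMPILED = {name: re.compile(f"(?=({pat}))") for name, pat in MOTIF_PATTERNS.items()}

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Synthetic default ISD reference profiles (one per simulated Env group);
#: real group consensi are figure-only in the literature and are supplied
#: by the user as plain 17-mers when available.
DEFAULT_ISD_PROFILES = (
    "LQNRRGLDLLFLKQGGL",
    "LQNRRGLDLLFLKRGGL",
    "LQNRRGLDLLFLKKGGL",
)


@dataclass
class OrfHit:
    """One open reading frame; interval is 0-based half-open on the input."""

    start: int
    end: int
    strand: str
    frame: int
    protein: str

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass
class IsdHit:
    start: int
    window: str
    residue14: str
    suppressive: bool | None
    score: int = 0


@dataclass
class EnvAnnotation:
    furin_site: int | None = None
    isd: IsdHit | None = None
    cxxc: list[int] = field(default_factory=list)
    cx_n_cc: list[tuple[int, int]] = field(default_factory=list)  # (n, position)
    tm_segment: tuple[int, int] | None = None
    architecture_valid: bool = False
    notes: str = ""


_STOPS = ("TAA", "TAG", "TGA")


def _orfs_one_strand(seq: str, min_len_aa: int, require_start: bool):
    hits = []
    for frame in range(3):
        i = frame
        start = None
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if start is None:
                if (not require_start and codon not in _STOPS) or codon == "ATG":
                    start = i
            if start is not None and codon in _STOPS:
                if (i - start) // 3 >= min_len_aa:
                    hits.append((start, i + 3, frame))
                start = None
            i += 3
        if start is not None and (i - start) // 3 >= min_len_aa:
            hits.append((start, i, frame))  # runs off the end, no stop
    return hits


def find_orfs(
    nt_seq: str, min_len_aa: int = 100, both_strands: bool = True, require_start: bool = True
) -> list[OrfHit]:
    """Scan all six frames for ORFs of at least ``min_len_aa`` codons.

    An ORF starts at ATG (or any sense codon when ``require_start`` is
    off) and ends at the first in-frame stop, or the sequence end.
    Intervals are reported in forward-strand coordinates of the input and
    include the stop codon; results come longest-first.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    if len(nt_seq) < 3:
        raise ValueError("sequence shorter than one codon")
    nt_seq = nt_seq.upper()
    out = []
    for s, e, frame in _orfs_one_strand(nt_seq, min_len_aa, require_start):
        prot = str(Seq(nt_seq[s:e]).translate()).rstrip("*")
        out.append(OrfHit(s, e, "+", frame, prot))
    if both_strands:
        rc = str(Seq(nt_seq).reverse_complement())
        for s, e, frame in _orfs_one_strand(rc, min_len_aa, require_start):
            prot = str(Seq(rc[s:e]).translate()).rstrip("*")
            out.append(OrfHit(len(nt_seq) - e, len(nt_seq) - s, "-", frame, prot))
    out.sort(key=lambda h: (-h.length_aa, h.start, h.strand))
    return out


def scan_simple_motifs(protein: str) -> dict[str, list[int]]:
    """All (possibly overlapping) matches of the simple Env/Gag motifs.

    Returns 0-based start positions per motif name; the residue X is
    tolerated in the input but never satisfies any pattern position.
    """
    protein = protein.upper()
    return {
        name: [m.start() for m in rex.finditer(protein)]
        for name, rex in _COMPILED.items()
    }


def locate_isd(
    protein: str,
    isd_reference_profiles=DEFAULT_ISD_PROFILES,
    min_score: int = 0,
) -> IsdHit | None:
    """Best 17-aa window against the reference profiles.

    The window is scored per column (1 for an exact residue match); the
    earliest best-scoring window wins. Residue 14 (1-based within the
    window) sets ``suppressive``: True for Q, False for R/K, None
    otherwise. Windows scoring below ``min_score`` are rejected.
    """
    if not isd_reference_profiles:
        raise ValueError("at least one ISD reference profile is required")
    for p in isd_reference_profiles:
        if len(p) != 17:
            raise ValueError("ISD profiles must be exactly 17 aa")
    if len(protein) < 17:
        raise ValueError("protein shorter than the 17-aa ISD window")
    protein = protein.upper()
    best = None
    for i in range(len(protein) - 16):
        window = protein[i : i + 17]
        score = max(
            sum(a == b for a, b in zip(window, prof)) for prof in isd_reference_profiles
        )
        if best is None or score > best[0]:
            best = (score, i, window)
    score, i, window = best
    if score < min_score:
        return None
    r14 = window[13]
    suppressive = True if r14 == "Q" else False if r14 in "RK" else None
    return IsdHit(start=i, window=window, residue14=r14, suppressive=suppressive, score=score)


def predict_tm(
    protein: str, window: int = 19, threshold: float = 1.6, merge_gap: int = 5
) -> list[tuple[int, int]]:
    """Hydrophobic (candidate transmembrane) segments.

    Maximal runs of sliding-window mean Kyte–Doolittle hydropathy at or
    above ``threshold``; runs separated by fewer than ``merge_gap``
    window positions are merged. Returns residue intervals.
    """
    protein = protein.upper()
    if len(protein) < window:
        raise ValueError("protein shorter than the hydropathy window")
    vals = [KYTE_DOOLITTLE.get(a, 0.0) for a in protein]
    n = len(protein) - window + 1
    means = [sum(vals[i : i + window]) / window for i in range(n)]
    above = [i for i in range(n) if means[i] >= threshold]
    if not above:
        return []
    runs = []
    run_start = prev = above[0]
    for i in above[1:]:
        if i - prev >= merge_gap:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))
    return [(s, e + window) for s, e in runs]


def annotate_env(
    protein: str,
    profiles=DEFAULT_ISD_PROFILES,
    isd_min_score: int = 12,
    tm_threshold: float = 1.6,
) -> EnvAnnotation:
    """Full Env feature annotation plus architecture validation.

    ``architecture_valid`` holds iff the features that are present occur
    in the canonical order furin < ISD < C-Xn-CC < TM (absent features
    are skipped); a protein with no features at all is vacuously valid
    and flagged in ``notes``.
    """
    ann = EnvAnnotation()
    hits = scan_simple_motifs(protein)
    ann.furin_site = hits["furin"][0] if hits["furin"] else None
    ann.cxxc = hits["cxxc"]
    ann.cx_n_cc = sorted(
        (n, p) for n in (5, 6, 7) for p in hits[f"cx{n}cc"]
    )
    if len(protein) >= 17:
        ann.isd = locate_isd(protein, profiles, min_score=isd_min_score)
    tms = predict_tm(protein, threshold=tm_threshold) if len(protein) >= 19 else []
    ann.tm_segment = tms[-1] if tms else None  # C-terminal-most segment

    order = []
    if ann.furin_site is not None:
        order.append(ann.furin_site)
    if ann.isd is not None:
        order.append(ann.isd.start)
    if ann.cx_n_cc:
        order.append(min(p for _, p in ann.cx_n_cc))
    if ann.tm_segment is not None:
        order.append(ann.tm_segment[0])
    if not order:
        ann.architecture_valid = True
        ann.notes = "no features"
    else:
        ann.architecture_valid = all(a < b for a, b in zip(order, order[1:]))
    return ann
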