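"""Structural classification, class assignment and the ERV naming scheme.

Structure tokens describe which parts of a provirus survive, e.g.
``LTR-gag-pol-env-LTR`` (complete), ``LTR-LTR`` (internal genes lost) or
``(LTR)-gag`` — parenthesised LTR meaning only a single LTR remains at
one end. Class labels (retroviral classes I-III and the Gypsy/Bel/Copia
superfamilies) are assigned by nearest-reference identity over the
reverse-transcriptase (RT) region, a deliberate surrogate for a full RT
phylogeny.

Names follow the three-part scheme ``<prefix>-<locus>-<species>``:
``ERV`` for class I-III elements (locus initialed E/AB/S for epsilon-,
alphabeta- or spuma-related), ``ERVL`` (ERV-like) for the rest. The
locus part is ``chrom.fragment.ordinal`` with the fragment index taken
from the 9-Mb segmentation, plus an optional trailing G/P/E marking a
gag/pol/env gene lying outside the LTR-to-LTR span, e.g.
``ERV-E5.1.38-DanRer`` or ``ERV-21.2.63E-DanRer``.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .detect import FRAGMENT_OVERLAP, FRAGMENT_SIZE, ErvElement, segment_chromosome

GENE_ORDER = ("gag", "pol", "env")

#: Classes that earn the plain "ERV" prefix; everything else is "ERVL".
RETROVIRAL_CLASSES = ("classI", "classII", "classIII")

#: Locus initial per retroviral class (epsilon-, alphabeta-, spuma-related).
CLASS_LETTER = {"classI": "E", "classII": "AB", "classIII": "S"}


def classify_structure(element: ErvElement) -> str:
    """Deterministic structure token from LTR/gene presence flags."""
    has5 = element.ltr5 is not None
    has3 = element.ltr3 is not None
    genes = [g for g in GENE_ORDER if g in element.genes]
    if not (has5 or has3 or genes):
        raise ValueError("element has no recognizable parts")
    parts = []
    if has5:
        parts.append("LTR" if has3 else "(LTR)")
    parts.extend(genes)
    if has3:
        parts.append("LTR" if has5 else "(LTR)")
    return "-".join(parts)


def structure_census(elements) -> pd.DataFrame:
    """Category counts and fractions over a cohort.

    Also reports (as DataFrame attrs) the fraction of elements retaining
    LTRs at both ends.
    """
    tokens = [classify_structure(e) if not isinstance(e, str) else e for e in elements]
    counts = Counter(tokens)
    total = sum(counts.values())
    df = pd.DataFrame(
        {
            "category": list(counts),
            "count": [counts[c] for c in counts],
        }
    ).sort_values("count", ascending=False, ignore_index=True)
    df["fraction"] = df["count"] / total if total else []
    df.attrs["both_ltr_fraction"] = (
        sum(n for c, n in counts.items() if c.startswith("LTR") and c.endswith("LTR"))
        / total
        if total
        else float("nan")
    )
    return df


_PANEL_ALIGNER = Align.PairwiseAligner()
_PANEL_ALIGNER.mode = "local"
_PANEL_ALIGNER.match_score = 1
_PANEL_ALIGNER.mismatch_score = -1
_PANEL_ALIGNER.open_gap_score = -2
_PANEL_ALIGNER.extend_gap_score = -1


def assign_class_by_reference(
    rt_seq: str, panel: dict[str, str], min_identity: float = 0.6
) -> tuple[str, float]:
    """Nearest-reference class over the RT region.

    Identity = local-alignment matches / min(query length, reference
    length), so a short spurious local hit cannot pass the floor. Ties go
    to the first-listed reference. Returns (label, identity) with label
    ``"unclassified"`` below ``min_identity``.
    """
    if not rt_seq:
        raise ValueError("empty query")
    if not panel:
        raise ValueError("empty reference panel")
    best_label, best_ident = "unclassified", 0.0
    for label, ref in panel.items():
        alns = _PANEL_ALIGNER.align(rt_seq.upper(), ref.upper())
        if len(alns) == 0:
            continue
        aln = alns[0]
        blocks_a, blocks_b = aln.aligned
        matches = 0
        for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
            matches += sum(x == y for x, y in zip(aln.target[a0:a1], aln.query[b0:b1]))
        ident = matches / min(len(rt_seq), len(ref))
        if ident > best_ident:
            best_label, best_ident = label, ident
    if best_ident < min_identity:
        return "unclassified", best_ident
    return best_label, best_ident


@dataclass(frozen=True)
class ErvName:
    prefix: str = "ERV"                 # ERV | ERVL
    class_letter: str = ""              # E | AB | S | ""
    chrom_token: str = "1"
    fragment_index: int = 1             # 1-based
    fragment_sub: str = ""              # optional lowercase sub-fragment letter
    ordinal: int = 1                    # 1-based rank within the fragment
    out_of_bound_suffix: str = ""       # G | P | E | ""
    species_token: str = "DanRer"

    def __post_init__(self):
        if self.prefix not in ("ERV", "ERVL"):
            raise ValueError(f"bad prefix {self.prefix!r}")
        if self.class_letter not in ("", "E", "AB", "S"):
            raise ValueError(f"bad class letter {self.class_letter!r}")
        if self.prefix == "ERVL" and self.class_letter:
            raise ValueError("ERVL names carry no class letter")
        if self.fragment_index < 1 or self.ordinal < 1:
            raise ValueError("fragment_index and ordinal are 1-based")
        if self.fragment_sub and not re.fullmatch(r"[a-z]", self.fragment_sub):
            raise ValueError("fragment_sub must be one lowercase letter")
        if self.out_of_bound_suffix not in ("", "G", "P", "E"):
            raise ValueError(f"bad out-of-bound suffix {self.out_of_bound_suffix!r}")
        if not re.fullmatch(r"\d+", self.chrom_token):
            raise ValueError("chrom_token must be numeric")
        if not re.fullmatch(r"[A-Za-z][A-Za-z0-9]*", self.species_token):
            raise ValueError("bad species token")


def format_name(fields: ErvName) -> str:
    """Render an :class:`ErvName` to its canonical string."""
    locus = (
        f"{fields.class_letter}{fields.chrom_token}."
        f"{fields.fragment_index}{fields.fragment_sub}.{fields.ordinal}"
        f"{fields.out_of_bound_suffix}"
    )
    return f"{fields.prefix}-{locus}-{fields.species_token}"


_NAME_RE = re.compile(
    r"^(?P<prefix>ERVL|ERV)-"
    r"(?P<letter>AB|E|S)?"
    r"(?P<chrom>\d+)\."
    r"(?P<frag>\d+)(?P<fragsub>[a-z])?\."
    r"(?P<ordinal>\d+)"
    r"(?P<suffix>[GPE])?"
    r"-(?P<species>[A-Za-z][A-Za-z0-9]*)$"
)


def parse_name(name: str) -> ErvName:
    """Inverse of :func:`format_name`; raises naming the offending part."""
    m = _NAME_RE.match(name)
    if m is None:
        # locate the failing part for the error message
        if not name.startswith(("ERV-", "ERVL-")):
            raise ValueError(f"bad prefix in {name!r}")
        if not name.endswith("-DanRer") and name.count("-") < 2:
            raise ValueError(f"missing species part in {name!r}")
        raise ValueError(f"malformed locus part in {name!r}")
    return ErvName(
        prefix=m["prefix"],
        class_letter=m["letter"] or "",
        chrom_token=m["chrom"],
        fragment_index=int(m["frag"]),
        fragment_sub=m["fragsub"] or "",
        ordinal=int(m["ordinal"]),
        out_of_bound_suffix=m["suffix"] or "",
        species_token=m["species"],
    )


def fragment_index_for(
    start: int,
    fragment_size: int = FRAGMENT_SIZE,
    overlap: int = FRAGMENT_OVERLAP,
) -> int:
    """1-based index of the earliest fragment containing ``start``.

    Elements starting inside a 2-kb overlap zone therefore belong to the
    earlier fragment.
    """
    step = fragment_size - overlap
    # earliest i with i*step <= start < i*step + fragment_size
    i = max(0, (start - fragment_size) // step + 1)
    return int(i) + 1


def assign_names(
    elements: list[ErvElement],
    chrom_lengths: dict[str, int] | None = None,
    species_token: str = "DanRer",
    fragment_size: int = FRAGMENT_SIZE,
    overlap: int = FRAGMENT_OVERLAP,
) -> list[ErvElement]:
    """Name every element in place (fragment index + within-fragment rank).

    Class I elements get the "E" initial even when the winning reference
    was not explicitly epsilon-related (flagged package-wide in run
    metadata); non class I-III elements get the ERVL prefix.
    """
    by_chrom_frag: dict[tuple[str, int], list[ErvElement]] = {}
    for el in elements:
        fi = fragment_index_for(el.start, fragment_size, overlap)
        by_chrom_frag.setdefault((el.chrom, fi), []).append(el)
    for (chrom, fi), group in by_chrom_frag.items():
        group.sort(key=lambda e: e.start)
        for rank, el in enumerate(group, start=1):
            retro = el.class_label in RETROVIRAL_CLASSES
            suffix = ""
            for g, (a, b) in el.genes.items():
                if a < el.start or b > el.end:
                    suffix = {"gag": "G", "pol": "P", "env": "E"}[g]
                    break
            chrom_token = re.sub(r"\D", "", chrom) or "0"
            fields = ErvName(
                prefix="ERV" if retro else "ERVL",
                class_letter=CLASS_LETTER.get(el.class_label, "") if retro else "",
                chrom_token=chrom_token,
                fragment_index=fi,
                ordinal=rank,
                out_of_bound_suffix=suffix,
                species_token=species_token,
            )
            el.name = format_name(fields)
    return elements
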