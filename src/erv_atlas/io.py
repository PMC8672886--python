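"""Plain-text readers/writers for the pipeline's interchange formats.

FASTA via Bio.SeqIO; BED6 with the raw score clipped to [0, 1000] (BED
convention) and the unclipped score kept in a TSV sidecar; a minimal GFF3
writer with LTR/gene child features; truth tables and expression inputs
as TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .detect import ErvElement
from .simulate import TruthRecord


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_bed(elements: list[ErvElement], path) -> None:
    """BED6; the name column holds the assigned name or element_id."""
    with open(path, "w") as fh:
        for el in sorted(elements, key=lambda e: (e.chrom, e.start)):
            score = int(min(max(el.score, 0), 1000))
            name = el.name or el.element_id
            fh.write(f"{el.chrom}\t{el.start}\t{el.end}\t{name}\t{score}\t{el.strand}\n")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return df


def write_truth_bed(truth: list[TruthRecord], path) -> None:
    """Truth BED: score column = age in Mya x 100, rounded."""
    with open(path, "w") as fh:
        for rec in truth:
            score = round(rec.spec.age_mya * 100)
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.element_id}\t{score}\t{rec.strand}\n"
            )


def write_truth_table(truth: list[TruthRecord], path) -> None:
    rows = []
    for rec in truth:
        rows.append(
            {
                "element_id": rec.element_id,
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "strand": rec.strand,
                "structure_category": rec.spec.structure_category,
                "age_mya": rec.spec.age_mya,
                "ltr_length": rec.spec.ltr_length,
                "class_label": rec.spec.class_label,
                "expected_divergence": rec.expected_divergence,
                "motifs": ",".join(m for m, _ in rec.planted_motif_coords),
                "ltr5": f"{rec.ltr5[0]}-{rec.ltr5[1]}" if rec.ltr5 else "",
                "ltr3": f"{rec.ltr3[0]}-{rec.ltr3[1]}" if rec.ltr3 else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_score_sidecar(elements: list[ErvElement], path) -> None:
    rows = [
        {"element_id": el.element_id, "name": el.name or "", "chrom": el.chrom,
         "start": el.start, "end": el.end, "score": el.score,
         "high_confidence": el.high_confidence, "class_label": el.class_label,
         **{f"score_{k}": v for k, v in el.components.items()}}
        for el in elements
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gff3(elements: list[ErvElement], path, source: str = "erv_atlas") -> None:
    """GFF3 with one parent feature per element and LTR/gene children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in sorted(elements, key=lambda e: (e.chrom, e.start)):
            eid = el.name or el.element_id
            fh.write(
                f"{el.chrom}\t{source}\tmobile_genetic_element\t{el.start + 1}\t{el.end}\t"
                f"{el.score:.1f}\t{el.strand}\t.\tID={eid};class={el.class_label}\n"
            )
            children = []
            if el.ltr5:
                children.append(("long_terminal_repeat", el.ltr5, "LTR5"))
            if el.ltr3:
                children.append(("long_terminal_repeat", el.ltr3, "LTR3"))
            for g, iv in el.genes.items():
                children.append(("CDS", iv, g))
            for ftype, (a, b), label in children:
                fh.write(
                    f"{el.chrom}\t{source}\t{ftype}\t{a + 1}\t{b}\t.\t{el.strand}\t.\t"
                    f"ID={eid}.{label};Parent={eid}\n"
                )


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "condition"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    return df


def read_lengths_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_chrom_sizes(genome: dict[str, str], path, gc: dict[str, float] | None = None) -> None:
    rows = [
        {"chrom": c, "length": len(s),
         "gc_percent": 100.0 * (s.count("G") + s.count("C")) / max(len(s), 1)
         if gc is None else gc[c]}
        for c, s in genome.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
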