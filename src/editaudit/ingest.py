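"""Readers and writers for genomes, annotations, and mutation tables.

The canonical mutation table is a TSV with columns
``sample_id  position  ref  alt  mut_class  read_fraction`` (1-based
positions, empty ref for insertions, empty alt for deletions).  A limited
GenomeDiff (.gd) reader ingests SNP/INS/DEL/MOB lines from resequencing
pipelines.  Subtraction of parental and intended mutations yields the
unintended-mutation list that all downstream statistics run on.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .records import GeneFeature, Genome, GenomeAnnotation, MutationRecord

#: strains are only reported as mutated when a call exceeds this share of
#: reads; applied as a strict "more than" bound
DEFAULT_READ_FRACTION_FLOOR = 0.10

TABLE_COLUMNS = ("sample_id", "position", "ref", "alt", "mut_class", "read_fraction")


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        return "genbank"
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    with open(path) as fh:
        first = fh.readline()
    return "genbank" if first.startswith("LOCUS") else "fasta"


def read_genome(
    path: str | Path,
    fmt: Optional[str] = None,
    record_id: Optional[str] = None,
    circular: bool = True,
) -> tuple[Genome, Optional[GenomeAnnotation]]:
    """Read a FASTA or GenBank genome; GenBank also yields its features.

    A multi-record file requires ``record_id``; an empty file is an error.
    """
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise ValueError(f"{path}: no sequence records found")
    if record_id is not None:
        records = [r for r in records if r.id == record_id]
        if not records:
            raise ValueError(f"{path}: no record with id {record_id!r}")
    if len(records) > 1:
        raise ValueError(
            f"{path}: {len(records)} records present; pass record_id to select one"
        )
    rec = records[0]
    if fmt == "genbank":
        topology = rec.annotations.get("topology", "")
        if topology:
            circular = topology == "circular"
    genome = Genome(sequence=str(rec.seq).upper(), circular=circular, name=rec.id)
    annotation = None
    if fmt == "genbank":
        feats = []
        for f in rec.features:
            if f.type not in ("CDS", "gene"):
                continue
            if f.type == "gene" and any(
                g.type == "CDS" and g.location is not None
                and f.location is not None
                and int(g.location.start) == int(f.location.start)
                for g in rec.features
            ):
                continue  # prefer the CDS feature for the same locus
            quals = f.qualifiers
            fid = (quals.get("locus_tag") or quals.get("gene") or [f"feat_{len(feats)}"])[0]
            frame = int(quals.get("codon_start", ["1"])[0]) - 1
            feats.append(
                GeneFeature(
                    feature_id=fid,
                    start=int(f.location.start) + 1,
                    end=int(f.location.end),
                    strand="+" if f.location.strand != -1 else "-",
                    frame=frame,
                )
            )
        annotation = GenomeAnnotation(
            features=feats, genome_length=len(genome), circular=circular
        )
    return genome, annotation


def read_annotation_gff3(
    path: str | Path, genome_length: int, circular: bool = True
) -> GenomeAnnotation:
    """Gene/CDS features from a GFF3 file (via gffutils, in-memory)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    for f in db.all_features():
        if f.featuretype not in ("CDS", "gene"):
            continue
        fid = f.attributes.get("ID", [f.id])[0]
        frame = int(f.frame) if f.frame not in (None, ".") else 0
        feats.append(
            GeneFeature(
                feature_id=fid,
                start=f.start,
                end=f.end,
                strand=f.strand if f.strand in ("+", "-") else "+",
                frame=frame,
            )
        )
    return GenomeAnnotation(
        features=feats, genome_length=genome_length, circular=circular
    )


# ---------------------------------------------------------------------------
# canonical mutation tables


def read_mutation_table(
    source: str | Path | io.TextIOBase,
    min_read_fraction: float = DEFAULT_READ_FRACTION_FLOOR,
) -> list[MutationRecord]:
    """Read the canonical TSV, dropping calls at or below the read-fraction
    floor (strictly "more than" the floor is kept).

    Malformed rows raise a single error listing the offending line numbers.
    """
    if isinstance(source, (str, Path)):
        fh = open(source)
        close = True
    else:
        fh, close = source, False
    try:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TABLE_COLUMNS:
            raise ValueError(
                f"bad header {header!r}; expected {list(TABLE_COLUMNS)}"
            )
        records = []
        bad: list[int] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                bad.append(lineno)
                continue
            sample_id, pos_s, ref, alt, mut_class, frac_s = parts
            try:
                rec = MutationRecord(
                    sample_id=sample_id,
                    position=int(pos_s),
                    ref=ref,
                    alt=alt,
                    mut_class=mut_class,
                    read_fraction=float(frac_s),
                )
            except (ValueError, TypeError):
                bad.append(lineno)
                continue
            if rec.read_fraction > min_read_fraction:
                records.append(rec)
        if bad:
            raise ValueError(f"malformed mutation-table rows at lines: {bad}")
        return records
    finally:
        if close:
            fh.close()


def format_fraction(x: float) -> str:
    """Canonical read-fraction formatting (round-trips through float)."""
    return format(x, ".6g")


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.position}\t{r.ref}\t{r.alt}\t{r.mut_class}\t"
                f"{format_fraction(r.read_fraction)}\n"
            )


# ---------------------------------------------------------------------------
# GenomeDiff (limited: SNP/INS/DEL/MOB mutation lines)

_GD_CLASSES = {"SNP": "SNV", "INS": "insertion", "DEL": "deletion", "MOB": "MOB"}


def read_genomediff(
    source: str | Path | io.TextIOBase,
    genome: Optional[Genome] = None,
    sample_id: Optional[str] = None,
    min_read_fraction: float = DEFAULT_READ_FRACTION_FLOOR,
) -> list[MutationRecord]:
    """Ingest SNP/INS/DEL/MOB lines of a GenomeDiff file.

    GenomeDiff mutation lines do not carry the reference base; it is filled
    from ``genome`` when provided and written as ``N`` placeholders
    otherwise.  ``frequency=`` fields give the read fraction (1.0 assumed
    for consensus calls).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        default_sample = Path(str(source)).stem
    else:
        text = source.read()
        default_sample = "sample"
    sample = sample_id or default_sample
    records = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        kind = parts[0]
        if kind not in _GD_CLASSES:
            continue
        position = int(parts[4])
        kv = dict(
            p.split("=", 1) for p in parts[5:] if "=" in p and not p[0].isdigit()
        )
        frac = float(kv.get("frequency", 1.0))
        ref = alt = ""
        if kind == "SNP":
            alt = parts[5]
            ref = genome.base(position) if genome else "N"
        elif kind == "INS":
            alt = parts[5]
            ref = ""
        elif kind == "DEL":
            size = int(parts[5])
            if genome:
                ref = "".join(genome.base(position + k) for k in range(size))
            else:
                ref = "N" * size
            alt = ""
        elif kind == "MOB":
            ref = ""
            alt = parts[5]  # repeat name; recorded for provenance
        rec = MutationRecord(
            sample_id=sample,
            position=position,
            ref=ref,
            alt=alt,
            mut_class=_GD_CLASSES[kind],
            read_fraction=frac,
        )
        if rec.read_fraction > min_read_fraction:
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# parental / intended subtraction


def subtract_known(
    records: Sequence[MutationRecord],
    parental_mutations: Iterable[tuple[int, str, str]] = (),
    intended_edits: Iterable[tuple[int, str, str]] = (),
    positional_tolerance: int = 0,
) -> list[MutationRecord]:
    """Remove parental-strain and intended-edit calls; the remainder is the
    unintended-mutation list.

    Exact (position, ref, alt) matches are removed.  Calls that are not
    exact matches but lie within ``positional_tolerance`` bp of an intended
    edit are kept and flagged ``near_intended`` rather than silently
    dropped.  Output is stably ordered by position.
    """
    parental = set(parental_mutations)
    intended = set(intended_edits)
    drop = parental | intended
    intended_positions = [p for p, _, _ in intended]
    out = []
    for rec in records:
        if rec.key in drop:
            continue
        if positional_tolerance and any(
            abs(rec.position - p) <= positional_tolerance for p in intended_positions
        ):
            rec = rec.with_flag("near_intended")
        out.append(rec)
    out.sort(key=lambda r: r.position)
    return out


def flag_recurrent(clones) -> None:
    """Flag identical (position, ref, alt) mutations seen in >=2 clones of
    one experiment as ``possibly_preexisting`` (they may predate editing);
    they still count toward per-clone totals."""
    from collections import Counter

    counts = Counter(
        m.key for c in clones for m in c.unintended_mutations
    )
    for c in clones:
        c.unintended_mutations = [
            m.with_flag("possibly_preexisting") if counts[m.key] >= 2 else m
            for m in c.unintended_mutations
        ]
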