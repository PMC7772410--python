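"""External formats and bundled reference tables.

FASTA in/out (via Biopython), the six-column evidence TSV, the literature
TSV, the gene-layout TSV, and machine-readable reproductions of the
study's three printed annotation tables. The genome-layout fixture
realizing the six-cluster gene-neighborhood figure is *synthetic*: the
figure shows gene arrangements but prints no coordinates, so the bundled
``fig3_layout_synthetic.tsv`` realizes the stated adjacency structure
(32 HP genes in six same-strand runs) with invented coordinates.
"""

from __future__ import annotations

import io as _io
import logging
import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .evidence import CHANNELS, EvidenceRecord, LiteratureEvidence
from .neighborhood import GeneLocus
from .physchem import STANDARD_RESIDUES

log = logging.getLogger(__name__)

#: the four candidate-selection keywords used for text-mining descriptions
#: (singular "protein" so both singular and plural descriptions match)
DEFAULT_HP_KEYWORDS = ("hypothetical protein", "unknown", "uncharacterized", "putative")

_PERMISSIVE_EXTRA = frozenset("BZXU")
_EC_FIELD_RE = re.compile(r"^(\d+|-)(\.(\d+|-)){3}$")


@dataclass(frozen=True)
class ProteinRecord:
    """A candidate protein: locus tag, description, amino-acid sequence."""

    locus_tag: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.locus_tag:
            raise ValidationError("locus_tag must be nonempty")
        if not self.sequence:
            raise ValidationError(f"{self.locus_tag}: empty sequence")


@dataclass(frozen=True)
class AnnotationTableRow:
    """One row of a printed annotation table."""

    locus_tags: tuple
    assigned_function: str
    gene_symbol: Optional[str]
    ec_number: Optional[str]
    section_label: str
    table: str = ""
    ec_raw: str = ""

    def __post_init__(self) -> None:
        if not self.locus_tags:
            raise ValidationError("locus_tags must be nonempty")
        if self.ec_number is not None and not _EC_FIELD_RE.match(self.ec_number):
            raise ValidationError(f"malformed EC number {self.ec_number!r}")


def normalize_locus_tag(tag: str) -> str:
    """Lowercase; bare 4-digit table forms are expanded to ``mru_XXXX``."""
    tag = tag.strip().casefold()
    if tag.isdigit():
        tag = f"mru_{tag}"
    return tag


def read_fasta(path: Union[str, Path], permissive: bool = False) -> List[ProteinRecord]:
    """Read protein FASTA; header token before whitespace is the locus tag.

    Residues outside the 20 standard codes raise unless ``permissive``,
    which additionally admits the ambiguity codes B, Z, X, U.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FormatError(f"{path}: not FASTA (first non-blank character is not '>')")
    allowed = STANDARD_RESIDUES | (_PERMISSIVE_EXTRA if permissive else frozenset())
    records = []
    seen = set()
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence body for header {rec.description!r}")
        bad = set(seq) - allowed
        if bad:
            raise ValidationError(
                f"{rec.id}: nonstandard residue(s) {sorted(bad)}"
                + ("" if permissive else " (use permissive=True for B/Z/X/U)")
            )
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate locus tag {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip()
        records.append(ProteinRecord(rec.id, desc, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: Union[str, Path]) -> None:
    """Write protein records as FASTA (60-column wrap)."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.locus_tag, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def select_hypothetical(
    records: Sequence[ProteinRecord],
    keywords: Sequence[str] = DEFAULT_HP_KEYWORDS,
) -> List[ProteinRecord]:
    """Case-insensitive substring keyword match on descriptions, order-preserving."""
    if not keywords:
        raise ValidationError("keywords must be nonempty")
    folded = [k.casefold() for k in keywords]
    return [r for r in records if any(k in r.description.casefold() for k in folded)]


_EVIDENCE_COLUMNS = ["locus_tag", "channel", "function_label", "identifier", "evalue", "source"]


def read_evidence_table(path: Union[str, Path]) -> List[EvidenceRecord]:
    """Read the six-column evidence TSV (optional signal_peptide/fold columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing evidence columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.channel not in CHANNELS:
            raise ValidationError(f"{path} line {i}: unknown channel {row.channel!r}")
        try:
            evalue = float(row.evalue)
        except ValueError:
            raise ValidationError(f"{path} line {i}: unparseable evalue {row.evalue!r}")
        if not (math.isfinite(evalue) and evalue >= 0):
            raise ValidationError(f"{path} line {i}: evalue must be nonnegative")
        sp = getattr(row, "signal_peptide", "")
        fold = getattr(row, "fold", "")
        records.append(
            EvidenceRecord(
                locus_tag=row.locus_tag,
                channel=row.channel,
                function_label=row.function_label,
                identifier=row.identifier,
                evalue=evalue,
                source=row.source,
                signal_peptide=None if sp == "" else sp in ("1", "true", "True"),
                fold=fold or None,
            )
        )
    return records


def write_evidence_table(records: Iterable[EvidenceRecord], path: Union[str, Path]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "locus_tag": r.locus_tag,
                "channel": r.channel,
                "function_label": r.function_label,
                "identifier": r.identifier,
                "evalue": repr(r.evalue),
                "source": r.source,
                "signal_peptide": "" if r.signal_peptide is None else int(r.signal_peptide),
                "fold": r.fold or "",
            }
        )
    pd.DataFrame(rows, columns=_EVIDENCE_COLUMNS + ["signal_peptide", "fold"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_literature_table(path: Union[str, Path]) -> List[LiteratureEvidence]:
    """Read the literature TSV: locus_tag, function_label, provenance_level, reference."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"locus_tag", "function_label", "provenance_level"}
    if needed - set(df.columns):
        raise FormatError(f"{path}: missing literature columns")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            level = int(row.provenance_level)
        except ValueError:
            raise ValidationError(f"{path} line {i}: bad provenance_level")
        records.append(
            LiteratureEvidence(
                locus_tag=row.locus_tag,
                function_label=row.function_label,
                provenance_level=level,
                reference=getattr(row, "reference", ""),
            )
        )
    return records


def write_literature_table(
    records: Iterable[LiteratureEvidence], path: Union[str, Path]
) -> None:
    rows = [
        {
            "locus_tag": r.locus_tag,
            "function_label": r.function_label,
            "provenance_level": r.provenance_level,
            "reference": r.reference,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["locus_tag", "function_label", "provenance_level", "reference"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _loci_from_df(df: pd.DataFrame, origin: str) -> List[GeneLocus]:
    loci = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError:
            raise ValidationError(f"{origin} line {i}: non-integer coordinates")
        is_hp = str(getattr(row, "is_hp", "1")) in ("1", "true", "True")
        label = str(getattr(row, "label", "")) or None
        loci.append(GeneLocus(row.locus_tag, start, end, row.strand, is_hp, label))
    loci.sort(key=lambda g: (g.start, g.end, g.locus_tag))
    for a, b in zip(loci, loci[1:]):
        if b.start <= a.end:
            log.warning("overlapping genes %s and %s", a.locus_tag, b.locus_tag)
    return loci


def read_gene_layout(path: Union[str, Path]) -> List[GeneLocus]:
    """Read a gene-layout TSV (locus_tag, start, end, strand[, is_hp, label]).

    Coordinates are 1-based inclusive; loci are returned sorted by start;
    overlaps are permitted but logged as warnings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if {"locus_tag", "start", "end", "strand"} - set(df.columns):
        raise FormatError(f"{path}: missing layout columns")
    return _loci_from_df(df, str(path))


def write_gene_layout(loci: Iterable[GeneLocus], path: Union[str, Path]) -> None:
    rows = [
        {
            "locus_tag": g.locus_tag,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "is_hp": int(g.is_hp),
            "label": g.label or "",
        }
        for g in loci
    ]
    pd.DataFrame(
        rows, columns=["locus_tag", "start", "end", "strand", "is_hp", "label"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _parse_ec(raw: str) -> Optional[str]:
    # multi-EC cells ("1.5.1.7| 1.5.1.8", "4.2.1.147/4.1.2.43"): keep the first
    raw = raw.strip()
    if not raw:
        return None
    first = re.split(r"[|/]", raw)[0].strip()
    if not _EC_FIELD_RE.match(first):
        raise ValidationError(f"malformed EC number {first!r}")
    return first


def _load_table(name: str, table: str) -> List[AnnotationTableRow]:
    try:
        text = resources.files("operomics.data").joinpath(name).read_text(encoding="utf-8")
    except FileNotFoundError:  # pragma: no cover - packaging error
        raise FormatError(f"bundled fixture {name} is missing from the package")
    df = pd.read_csv(_io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
    rows = []
    for row in df.itertuples(index=False):
        tags = tuple(
            normalize_locus_tag(t) for t in row.locus_tags.split("|") if t.strip()
        )
        rows.append(
            AnnotationTableRow(
                locus_tags=tags,
                assigned_function=row.assigned_function,
                gene_symbol=row.gene_symbol or None,
                ec_number=_parse_ec(row.ec_number),
                section_label=row.section_label,
                table=table,
                ec_raw=row.ec_number,
            )
        )
    return rows


def load_paper_tables(which: Optional[Sequence[str]] = None) -> List[AnnotationTableRow]:
    """Load the bundled reproductions of the three printed annotation tables.

    ``which`` selects a subset of {"table1", "table2", "table3"}; default all.
    """
    names = which or ("table1", "table2", "table3")
    rows: List[AnnotationTableRow] = []
    for t in names:
        rows.extend(_load_table(f"{t}.tsv", t))
    return rows


def load_tables_meta() -> Dict[str, float]:
    """Headline counts printed in the study text, as recorded (not reconciled)."""
    text = resources.files("operomics.data").joinpath("tables_meta.tsv").read_text()
    out = {}
    for ln in text.splitlines()[1:]:
        if ln.strip():
            k, v = ln.split("\t")
            out[k] = float(v)
    return out


def load_fig3_layout() -> List[GeneLocus]:
    """The synthetic genome-layout fixture realizing the six-cluster figure."""
    text = resources.files("operomics.data").joinpath(
        "fig3_layout_synthetic.tsv"
    ).read_text(encoding="utf-8")
    df = pd.read_csv(_io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
    return _loci_from_df(df, "fig3_layout_synthetic.tsv")


def load_synonyms(path: Union[str, Path, None] = None) -> Dict[str, str]:
    """Load a two-column synonym map TSV (variant → canonical); default bundled."""
    if path is None:
        text = resources.files("operomics.data").joinpath("synonyms.tsv").read_text(
            encoding="utf-8"
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    out = {}
    for ln in text.splitlines()[1:]:
        if ln.strip():
            variant, canonical = ln.split("\t")[:2]
            out[variant] = canonical
    return out
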