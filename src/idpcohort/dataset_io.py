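"""Sequence and annotation-table input for disorder cohort analysis.

Reads multi-record FASTA files into :class:`ProteinRecord` objects and the
tab-separated cohort annotation table (one row per protein: predictor disorder
contents, MoRF and ANCHOR-indicated binding-site intervals, complex-group
label) into :class:`AnnotationRow` objects.  All residue coordinates are
1-based inclusive, matching the printed interval notation (``"15-32"``);
conversion to 0-based happens only at array boundaries inside other modules.

The packaged cohort of 109 yeast spliceosomal proteins is available through
:func:`load_spliceosome_table`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as _ilr
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

__all__ = [
    "STANDARD_AA",
    "AMBIGUOUS_AA",
    "ProteinRecord",
    "Interval",
    "AnnotationRow",
    "ValidationIssue",
    "ValidationReport",
    "read_fasta",
    "read_annotation_table",
    "write_annotation_table",
    "load_spliceosome_table",
    "interval_length",
    "overlaps",
    "COMPLEX_GROUPS",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "XBZUO"
_VALID_CHARS = frozenset(STANDARD_AA + AMBIGUOUS_AA)

COMPLEX_GROUPS = (
    "Sm", "U1", "U2", "U5", "U4/U6", "U4/U6.U5", "Lsm", "RES", "NTC",
    "NTC-related", "Early", "Known", "Step2", "Disassembly", "CBP", "Other",
)

_ANNOTATION_COLUMNS = [
    "accession", "protein_name", "gene_name", "complex_group", "mw_kda",
    "length", "fit", "vlxt", "foldindex", "ronn", "morfs", "aibs",
    "human_ortholog", "pdb",
]

_CONTENT_PREDICTORS = ("fit", "vlxt", "foldindex", "ronn")


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence; the unit of per-residue analysis."""

    accession: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in _VALID_CHARS:
                raise ValueError(
                    f"{self.accession}: invalid residue {ch!r} at position {pos}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """1-based inclusive residue interval, ``start <= end``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.start}-{self.end}")

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


def interval_length(iv: Interval) -> int:
    """Number of residues covered: ``end - start + 1``."""
    return iv.end - iv.start + 1


def overlaps(a: Interval, b: Interval) -> bool:
    """True iff the two closed intervals share at least one residue."""
    return max(a.start, b.start) <= min(a.end, b.end)


@dataclass(frozen=True)
class ValidationIssue:
    field: str
    raw: str
    problem: str
    severity: Literal["warning", "error"] = "warning"


@dataclass
class ValidationReport:
    """Per-row record of malformed fields; empty iff the row passed strictly."""

    accession: str
    issues: list[ValidationIssue] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.issues)

    def add(self, fieldname: str, raw: str, problem: str,
            severity: Literal["warning", "error"] = "warning") -> None:
        self.issues.append(ValidationIssue(fieldname, raw, problem, severity))


@dataclass
class AnnotationRow:
    """One annotation-table row: scores, binding-site intervals, complex group.

    ``morfs``/``aibs`` hold only the intervals that validated against the row
    length; malformed tokens (``end < start`` or ``end > length``) are carried
    in ``flagged_morfs``/``flagged_aibs`` so counts stay auditable.
    """

    accession: str
    protein_name: str
    gene_name: str
    complex_group: str
    mw_kda: float
    length: int
    content_scores: dict[str, float]
    morfs: list[Interval] = field(default_factory=list)
    aibs: list[Interval] = field(default_factory=list)
    flagged_morfs: list[str] = field(default_factory=list)
    flagged_aibs: list[str] = field(default_factory=list)
    human_ortholog: str = ""
    pdb_entries: list[str] = field(default_factory=list)
    report: ValidationReport | None = None


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file.

    The header token before the first whitespace becomes the accession; the
    remainder of the header line becomes the name.  Raises ``ValueError`` for
    empty entries or characters outside the 20 standard residues plus the
    ambiguity codes X, B, Z, U, O.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for FASTA entry {rec.id!r}")
        name = rec.description[len(rec.id):].strip() or rec.id
        records.append(ProteinRecord(accession=rec.id, name=name, sequence=seq))
    return records


_INTERVAL_RE = re.compile(r"^(\d+)-(\d+)$")


def _parse_interval_list(
    cell: str, length: int, fieldname: str, report: ValidationReport,
    policy: str,
) -> tuple[list[Interval], list[str]]:
    valid: list[Interval] = []
    flagged: list[str] = []
    for token in filter(None, (t.strip() for t in cell.split(";"))):
        m = _INTERVAL_RE.match(token)
        problem = None
        if not m:
            problem = "unparseable interval token"
        else:
            start, end = int(m.group(1)), int(m.group(2))
            if start < 1 or end < start:
                problem = "end precedes start (or start < 1)"
            elif end > length:
                problem = f"end {end} exceeds protein length {length}"
        if problem is None:
            valid.append(Interval(int(m.group(1)), int(m.group(2))))
        else:
            if policy == "strict":
                raise ValueError(
                    f"{report.accession}: {fieldname} token {token!r}: {problem}"
                )
            report.add(fieldname, token, problem, "warning")
            flagged.append(token)
    valid.sort()
    return valid, flagged


def read_annotation_table(
    path: str | Path, policy: Literal["strict", "lenient"] = "lenient",
) -> list[AnnotationRow]:
    """Read the tab-separated cohort annotation table.

    Interval cells are semicolon-separated ``start-end`` tokens; an empty cell
    is the empty list.  In lenient mode (the default — the printed source
    table contains malformed tokens) intervals failing validation are moved to
    the row's flagged list with a warning recorded on its report; strict mode
    raises on the first malformed token and on duplicate accessions.
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown policy {policy!r}")
    path = Path(path)
    rows: list[AnnotationRow] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ANNOTATION_COLUMNS:
            raise ValueError(
                f"unexpected annotation header {header!r}; "
                f"expected {_ANNOTATION_COLUMNS!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(_ANNOTATION_COLUMNS):
                raise ValueError(f"line {lineno}: expected "
                                 f"{len(_ANNOTATION_COLUMNS)} columns")
            rec = dict(zip(_ANNOTATION_COLUMNS, cells))
            if rec["complex_group"] not in COMPLEX_GROUPS:
                raise ValueError(
                    f"line {lineno}: unknown complex group "
                    f"{rec['complex_group']!r}"
                )
            acc = rec["accession"]
            report = ValidationReport(acc)
            if acc in seen:
                if policy == "strict":
                    raise ValueError(f"duplicate accession {acc!r}")
                report.add("accession", acc, "duplicate accession (kept)",
                           "warning")
            seen.add(acc)
            length = int(rec["length"])
            scores = {}
            for pred in _CONTENT_PREDICTORS:
                val = float(rec[pred])
                if not 0.0 <= val <= 1.0:
                    raise ValueError(
                        f"line {lineno}: {pred} score {val} outside [0,1]"
                    )
                scores[pred] = val
            morfs, fm = _parse_interval_list(rec["morfs"], length, "morfs",
                                             report, policy)
            aibs, fa = _parse_interval_list(rec["aibs"], length, "aibs",
                                            report, policy)
            rows.append(AnnotationRow(
                accession=acc,
                protein_name=rec["protein_name"],
                gene_name=rec["gene_name"],
                complex_group=rec["complex_group"],
                mw_kda=float(rec["mw_kda"]),
                length=length,
                content_scores=scores,
                morfs=morfs,
                aibs=aibs,
                flagged_morfs=fm,
                flagged_aibs=fa,
                human_ortholog=rec["human_ortholog"],
                pdb_entries=[p for p in rec["pdb"].split(";") if p],
                report=report,
            ))
    return rows


def _fmt_float(x: float) -> str:
    # keep the printed two-decimal score / one-decimal MW style stable
    return f"{x:g}"


def write_annotation_table(rows: Iterable[AnnotationRow],
                           path: str | Path) -> None:
    """Write rows back to the annotation TSV (round-trips with the reader).

    Flagged tokens are re-emitted after the valid intervals so no information
    is lost across a load/save cycle.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_ANNOTATION_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join([
                r.accession, r.protein_name, r.gene_name, r.complex_group,
                _fmt_float(r.mw_kda), str(r.length),
                *(f"{r.content_scores[p]:.2f}" for p in _CONTENT_PREDICTORS),
                ";".join([str(iv) for iv in r.morfs] + r.flagged_morfs),
                ";".join([str(iv) for iv in r.aibs] + r.flagged_aibs),
                r.human_ortholog, ";".join(r.pdb_entries),
            ]) + "\n")


def packaged_data_path(name: str) -> Path:
    """Path to a file in the packaged data directory."""
    return Path(str(_ilr.files("idpcohort").joinpath("data", name)))


def load_spliceosome_table(
    policy: Literal["strict", "lenient"] = "lenient",
) -> list[AnnotationRow]:
    """Load the packaged 109-protein yeast spliceosome annotation table."""
    return read_annotation_table(packaged_data_path("spliceosome109.tsv"),
                                 policy=policy)
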