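"""Reading and writing of alignments, support trees, and specimen tables.

The external formats are deliberately plain: FASTA for alignments and OTU
representatives, Newick with numeric internal-node labels for bootstrap- or
likelihood-supported trees, and headered TSV for specimen metadata and
morphometric measurements.  Everything read is validated into the package's
domain types before any analysis touches it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Sentinel group label for specimens that belong to no delimited group.
UNASSIGNED = "UNASSIGNED"

#: IUPAC nucleotide one-letter codes plus the alignment gap character.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")


class FormatError(ValueError):
    """Malformed external input (bad FASTA/Newick/TSV syntax or content)."""


class AlignmentError(FormatError):
    """Sequences that cannot form a valid fixed-length alignment."""


@dataclass(frozen=True)
class Alignment:
    """An equal-length nucleotide alignment with unique, ordered identifiers."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids: {dup}")
        if any(not rid for rid in ids):
            raise FormatError("empty sequence id")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        if self.length < 1:
            raise AlignmentError("alignment length must be >= 1")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def sequence(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)

    def to_dict(self) -> dict[str, str]:
        return dict(self.records)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        keep = dict(self.records)
        return Alignment(tuple((i, keep[i]) for i in ids))


def _normalize(seq: str, rid: str, alphabet_policy: str) -> str:
    seq = seq.upper()
    bad = set(seq) - IUPAC_CHARS
    if not bad:
        return seq
    if alphabet_policy == "strict":
        raise FormatError(
            f"sequence {rid!r} contains non-IUPAC characters: {sorted(bad)}"
        )
    if alphabet_policy == "permissive":
        logger.warning(
            "sequence %r: mapping %d non-IUPAC character(s) %s to N",
            rid, sum(seq.count(c) for c in bad), sorted(bad),
        )
        return "".join("N" if c in bad else c for c in seq)
    raise ValueError(f"unknown alphabet policy: {alphabet_policy!r}")


def read_alignment(path: str | Path, alphabet_policy: str = "strict") -> Alignment:
    """Read a FASTA alignment, upper-casing residues and enforcing invariants.

    ``alphabet_policy='permissive'`` maps characters outside the IUPAC set to
    ``N`` with a logged warning; ``'strict'`` rejects them.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, _normalize(str(rec.seq), rec.id, alphabet_policy)))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment(tuple(records))


def write_alignment(aln: Alignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in aln.records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_newick_with_support(path: str | Path, support_scale: str = "auto",
                             strict: bool = True):
    """Read a Newick tree whose internal-node labels are bootstrap supports.

    Supports are normalized to percent in [0, 100]. ``support_scale`` is
    ``'percent'``, ``'fraction'``, or ``'auto'`` (fractional if every value
    is <= 1).  Under ``strict``, a non-numeric internal label raises
    :class:`FormatError`; otherwise it is ignored with a warning.
    """
    from .tree import SupportTree  # deferred: tree module builds on this one

    return SupportTree.from_newick_file(path, support_scale=support_scale,
                                        strict=strict)


def write_newick(tree, path: str | Path, decimals: int = 3) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(decimals=decimals))


# ---------------------------------------------------------------------------
# specimen and morphometric tables

SPECIMEN_COLUMNS = ("group", "nid", "species", "site", "location", "marker",
                    "accession")
MORPH_COLUMNS = ("nid", "stage", "tail_length", "anal_body_width",
                 "amphid_width", "neck_width")

#: Printed footnote marker used for specimens not assigned to any group.
_FOOTNOTE_UNASSIGNED = "a"


@dataclass(frozen=True)
class SpecimenTable:
    """Specimen metadata: one row per specimen (NID unique).

    ``df`` carries the parsed columns; ``markers`` is a frozenset drawn from
    {COI, 18S} and ``accessions`` a tuple aligned with the markers.  A blank
    group cell or the printed unassigned footnote becomes ``UNASSIGNED``.
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    @property
    def nids(self) -> tuple[str, ...]:
        return tuple(self.df["nid"])

    def groups(self) -> dict[str, tuple[str, ...]]:
        """Group label -> member NIDs, excluding unassigned specimens."""
        out: dict[str, list[str]] = {}
        for nid, grp in zip(self.df["nid"], self.df["group"]):
            if grp != UNASSIGNED:
                out.setdefault(grp, []).append(nid)
        return {g: tuple(v) for g, v in out.items()}

    def with_marker(self, marker: str) -> pd.DataFrame:
        return self.df[self.df["markers"].map(lambda m: marker in m)]


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        # TSV is the canonical dialect; fall back to comma if no tabs present
        head = Path(path).read_text().splitlines()[0] if Path(path).exists() else ""
        sep = "\t" if "\t" in head else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_specimen_table(path: str | Path, sep: str | None = None) -> SpecimenTable:
    df = _read_table(path, sep)
    missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"specimen table missing column(s): {missing}")
    if df["nid"].duplicated().any():
        dups = sorted(df.loc[df["nid"].duplicated(), "nid"])
        raise FormatError(f"duplicate NIDs in specimen table: {dups}")
    group = df["group"].str.strip()
    df = df.assign(
        group=group.where(~group.isin(["", _FOOTNOTE_UNASSIGNED]), UNASSIGNED),
        markers=df["marker"].str.split().map(frozenset),
        accessions=df["accession"].str.split().map(tuple),
    )
    bad = sorted(set().union(*df["markers"]) - {"COI", "18S"})
    if bad:
        raise FormatError(f"unknown marker label(s): {bad}")
    return SpecimenTable(df)


@dataclass(frozen=True)
class MorphTable:
    """Per-specimen morphometric measurements (micrometres).

    Tail length and anal body width are required positive numbers; amphid
    and neck widths may be missing (NA), in which case the derived
    amphid/neck ratio is undefined for that specimen.  Extra columns (group,
    printed ratios, morphotype labels) are preserved untouched.
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)


def read_morph_table(path: str | Path, sep: str | None = None) -> MorphTable:
    df = _read_table(path, sep)
    missing = [c for c in MORPH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"morphometric table missing column(s): {missing}")
    num_cols = ["tail_length", "anal_body_width", "amphid_width", "neck_width"]
    for col in num_cols:
        raw = df[col].str.strip()
        vals = pd.to_numeric(raw.replace({"NA": None, "": None}), errors="coerce")
        bad = raw.notna() & ~raw.isin(["NA", ""]) & vals.isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise FormatError(f"non-numeric value {raw[bad.idxmax()]!r} in "
                              f"column {col!r} at line {row}")
        df[col] = vals
    for col in ("tail_length", "anal_body_width"):
        if df[col].isna().any():
            row = int(df[col].isna().idxmax()) + 2
            raise FormatError(f"missing required measurement {col!r} at line {row}")
        if (df[col] <= 0).any():
            row = int((df[col] <= 0).idxmax()) + 2
            raise FormatError(f"non-positive {col!r} at line {row}")
    for col in ("amphid_width", "neck_width"):
        if ((df[col] <= 0) & df[col].notna()).any():
            raise FormatError(f"non-positive value in column {col!r}")
    stages = set(df["stage"].str.strip())
    if not stages <= {"F", "J"}:
        raise FormatError(f"unknown life stage label(s): {sorted(stages - {'F','J'})}")
    return MorphTable(df)
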