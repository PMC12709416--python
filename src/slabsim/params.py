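"""Residue parameters, sequences, regions, and composition statistics.

The one-bead-per-residue model assigns each amino acid a bead diameter
``sigma`` (nm), a "stickiness" ``lam`` in [0, 1] scaling the attractive part
of the pair potential, a charge (elementary charges) and a mass (g/mol).
Pairwise parameters are arithmetic means of the per-residue values.

A packaged table with the published CALVADOS2 values ships as the default
(:func:`default_table`); tests and synthetic studies use their own tables, so
nothing downstream depends on that file being authoritative.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

CANONICAL_CODES = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "CANONICAL_CODES",
    "ResidueParams",
    "ParameterTable",
    "SequenceRecord",
    "Region",
    "ParameterTableError",
    "load_parameter_table",
    "default_table",
    "pair_params",
    "extract_region",
    "composition_fraction",
    "assign_charges",
    "read_fasta",
    "write_fasta",
    "MUT16_REGIONS",
]


class ParameterTableError(ValueError):
    """Malformed, incomplete, or duplicated parameter-table input."""


@dataclass(frozen=True)
class ResidueParams:
    """Per-residue bead parameters."""

    code: str
    sigma: float  # nm
    lam: float  # unitless stickiness in [0, 1]
    charge: float  # e
    mass: float  # g/mol

    def __post_init__(self) -> None:
        if self.code not in CANONICAL_CODES or len(self.code) != 1:
            raise ParameterTableError(f"non-canonical residue code {self.code!r}")
        if not self.sigma > 0:
            raise ParameterTableError(f"sigma must be > 0 for {self.code}")
        if not 0.0 <= self.lam <= 1.0:
            raise ParameterTableError(f"lambda must be in [0,1] for {self.code}")
        if not self.mass > 0:
            raise ParameterTableError(f"mass must be > 0 for {self.code}")


@dataclass(frozen=True)
class ParameterTable:
    """Complete 20-residue parameter set with provenance label."""

    entries: Mapping[str, ResidueParams]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        missing = sorted(set(CANONICAL_CODES) - set(self.entries))
        extra = sorted(set(self.entries) - set(CANONICAL_CODES))
        if missing or extra:
            raise ParameterTableError(
                f"table must contain exactly the 20 canonical residues; "
                f"missing={missing} extra={extra}"
            )

    def __getitem__(self, code: str) -> ResidueParams:
        try:
            return self.entries[code]
        except KeyError:
            raise KeyError(f"unknown residue code {code!r}") from None

    def arrays(self, residues: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-bead (sigma, lam, charge, mass) arrays for a residue string."""
        p = [self[c] for c in residues]
        return (
            np.array([x.sigma for x in p]),
            np.array([x.lam for x in p]),
            np.array([x.charge for x in p]),
            np.array([x.mass for x in p]),
        )

    def with_his_charge(self, his_charge: float) -> "ParameterTable":
        entries = dict(self.entries)
        entries["H"] = replace(entries["H"], charge=his_charge)
        return ParameterTable(entries, self.provenance)


def load_parameter_table(source, provenance: str | None = None) -> ParameterTable:
    """Load a parameter table from delimited text.

    Expected columns: ``code  sigma_nm  lambda  charge_e  mass_gmol``
    (tab- or whitespace-separated, one row per residue).
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep=r"\s+")
        label = provenance or str(source)
    else:
        df = pd.read_csv(source, sep=r"\s+")
        label = provenance or "stream"
    required = {"code", "sigma_nm", "lambda", "charge_e", "mass_gmol"}
    if not required.issubset(df.columns):
        raise ParameterTableError(
            f"missing columns {sorted(required - set(df.columns))}"
        )
    entries: dict[str, ResidueParams] = {}
    for i, row in df.iterrows():
        code = str(row["code"]).strip()
        if code in entries:
            raise ParameterTableError(f"duplicate residue {code!r} at row {i}")
        try:
            entries[code] = ResidueParams(
                code=code,
                sigma=float(row["sigma_nm"]),
                lam=float(row["lambda"]),
                charge=float(row["charge_e"]),
                mass=float(row["mass_gmol"]),
            )
        except (TypeError, ValueError) as exc:
            raise ParameterTableError(f"malformed row {i} ({code!r}): {exc}") from exc
    if len(entries) < 20:
        raise ParameterTableError(
            f"incomplete table: {len(entries)} residues, need all 20"
        )
    return ParameterTable(entries, label)


def default_table() -> ParameterTable:
    """The packaged CALVADOS2-style table (provenance ``"CALVADOS2"``)."""
    text = resources.files("slabsim.data").joinpath("calvados2.tsv").read_text()
    return load_parameter_table(_io.StringIO(text), provenance="CALVADOS2")


def pair_params(a: str, b: str, table: ParameterTable) -> tuple[float, float]:
    """Arithmetic-mean combination rule: returns (sigma_ij, lam_ij)."""
    pa, pb = table[a], table[b]
    return 0.5 * (pa.sigma + pb.sigma), 0.5 * (pa.lam + pb.lam)


@dataclass(frozen=True)
class SequenceRecord:
    """An amino-acid sequence with its numbering in the parent protein."""

    id: str
    residues: str
    numbering_offset: int = 1  # number of the first residue (1-based)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        bad = sorted({c for c in self.residues if c not in CANONICAL_CODES})
        if bad:
            raise ValueError(f"non-canonical residues {bad} in {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def first(self) -> int:
        return self.numbering_offset

    @property
    def last(self) -> int:
        return self.numbering_offset + len(self.residues) - 1


@dataclass(frozen=True)
class Region:
    """1-based inclusive residue range in parent-protein numbering."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name!r}: start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


#: Region boundaries of the MUT-16 scaffold used throughout this package.
#: FFR defaults to 773-944 (the simulated and purified construct); the
#: alternative 773-945 boundary that also appears in the literature is
#: exposed as "FFR_945".
MUT16_REGIONS: dict[str, Region] = {
    "M8BR": Region("M8BR", 633, 772),
    "FFR": Region("FFR", 773, 944),
    "FFR_945": Region("FFR_945", 773, 945),
    "M8BR_FFR": Region("M8BR_FFR", 633, 944),
}

#: Aromatic residues used for composition statistics (His excluded).
AROMATIC = frozenset("FYW")


def extract_region(seq: SequenceRecord, region: Region) -> SequenceRecord:
    """Slice a sequence by parent-protein numbering (1-based inclusive)."""
    if region.start < seq.first or region.end > seq.last:
        raise IndexError(
            f"region {region.name!r} [{region.start},{region.end}] outside "
            f"sequence numbering [{seq.first},{seq.last}]"
        )
    i0 = region.start - seq.numbering_offset
    i1 = region.end - seq.numbering_offset + 1
    return SequenceRecord(
        id=f"{seq.id}/{region.name}",
        residues=seq.residues[i0:i1],
        numbering_offset=region.start,
    )


def composition_fraction(seq: SequenceRecord, residue_set: Iterable[str]) -> float:
    """Percentage of residues belonging to ``residue_set`` (0-100)."""
    members = set(residue_set)
    n = len(seq)
    if n == 0:  # unreachable through the constructor; guard anyway
        raise ValueError("composition of an empty sequence is undefined")
    return 100.0 * sum(c in members for c in seq.residues) / n


def assign_charges(
    seq: SequenceRecord,
    table: ParameterTable,
    termini_charged: bool = True,
    his_charge: float = 0.0,
) -> np.ndarray:
    """Per-bead charge vector (e).

    Table charges are used per residue; His is set to ``his_charge``; with
    ``termini_charged``, +1e is added to the first bead (amine terminus) and
    -1e to the last (carboxyl terminus). A single-residue chain carries both.
    """
    q = np.array(
        [his_charge if c == "H" else table[c].charge for c in seq.residues],
        dtype=float,
    )
    if termini_charged:
        q[0] += 1.0
        q[-1] -= 1.0
    return q


def read_fasta(path) -> list[SequenceRecord]:
    """Read single- or multi-record FASTA into :class:`SequenceRecord` list.

    A trailing ``/start-end`` in the record id (UniProt-style) sets the
    numbering offset; otherwise numbering starts at 1.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        offset = 1
        rid = rec.id
        if "/" in rid:
            head, _, rng = rid.rpartition("/")
            if "-" in rng:
                a, _, _b = rng.partition("-")
                if a.isdigit():
                    offset = int(a)
                    rid = head
        out.append(SequenceRecord(id=rid, residues=str(rec.seq).upper(), numbering_offset=offset))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [
        _BioSeqRecord(
            Seq(r.residues),
            id=f"{r.id}/{r.first}-{r.last}" if r.numbering_offset != 1 else r.id,
            description="",
        )
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")
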