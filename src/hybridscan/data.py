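"""Core data model and file I/O for the species-delimitation pipeline.

The pipeline works on three kinds of raw material:

* diploid multilocus microsatellite genotypes, where alleles are PCR
  fragment sizes in base pairs (codominant, multi-allelic markers);
* aligned mitochondrial DNA sequences (COI / cyt b barcoding fragments);
* per-sample metadata: the species label assigned in the field from
  morphology, the sampling site and region, and body measurements.

Interchange formats are the de-facto standards of the field: GenePop text
files (2- and 3-digit allele codes) and a long-form genotype CSV for
microsatellites, FASTA for alignments, and a plain CSV for metadata.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencyTable",
    "SampleMetadata",
    "SequenceAlignment",
    "GenotypeParseError",
    "read_genotypes_genepop",
    "write_genotypes_genepop",
    "read_genotypes_csv",
    "write_genotypes_csv",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_metadata_csv",
    "write_metadata_csv",
    "allele_frequencies",
]

MISSING = 0  # sentinel allele code: genotype (0, 0) means "not typed"


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates its dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals × loci diploid allele calls, plus a group label per individual.

    Alleles are positive integers (fragment sizes in bp). Calls are stored
    as an ``(n_individuals, n_loci, 2)`` integer array with each non-missing
    pair sorted ascending; a missing call is ``(0, 0)``. Partial calls
    (one allele known) are not representable: they are treated as missing.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, m = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {m}, 2)"
            )
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual IDs")
        if len(set(self.loci)) != m:
            raise ValueError("duplicate locus names")
        if (self.calls < 0).any():
            raise ValueError("allele labels must be positive integers")
        # canonicalise: sort each pair ascending, collapse half-calls to missing
        self.calls = np.sort(self.calls, axis=2)
        half = (self.calls[:, :, 0] == MISSING) & (self.calls[:, :, 1] != MISSING)
        self.calls[half] = MISSING

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def call(self, individual: str, locus: str) -> tuple[int, int] | None:
        """Return the allele pair, or None if missing."""
        i = self.individuals.index(individual)
        j = self.loci.index(locus)
        a, b = self.calls[i, j]
        return None if a == MISSING else (int(a), int(b))

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) array, True where untyped."""
        return self.calls[:, :, 0] == MISSING

    def n_missing(self) -> int:
        return int(self.missing_mask().sum())

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.group_of.get(ind, ""), None)
        return list(seen)

    def subset(
        self,
        individuals: Iterable[str] | None = None,
        loci: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        inds = list(individuals) if individuals is not None else self.individuals
        locs = list(loci) if loci is not None else self.loci
        ii = [self.individuals.index(x) for x in inds]
        jj = [self.loci.index(x) for x in locs]
        calls = self.calls[np.ix_(ii, jj)]
        groups = {x: self.group_of[x] for x in inds if x in self.group_of}
        return GenotypeMatrix(inds, locs, calls.copy(), groups)

    def concat(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if self.loci != other.loci:
            raise ValueError("locus sets differ")
        return GenotypeMatrix(
            self.individuals + other.individuals,
            self.loci,
            np.concatenate([self.calls, other.calls], axis=0),
            {**self.group_of, **other.group_of},
        )

    def typing_rate(self, locus: str, individuals: Iterable[str] | None = None) -> float:
        """Fraction of (selected) individuals successfully typed at a locus."""
        j = self.loci.index(locus)
        if individuals is None:
            col = self.calls[:, j, 0]
        else:
            ii = [self.individuals.index(x) for x in individuals]
            col = self.calls[ii, j, 0]
        if col.size == 0:
            return 0.0
        return float((col != MISSING).mean())


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele relative frequencies for one group of individuals."""

    group: str
    freqs: dict[str, dict[int, float]]
    n_typed: dict[str, int]

    def __post_init__(self) -> None:
        for locus, f in self.freqs.items():
            if f:
                s = sum(f.values())
                if abs(s - 1.0) > 1e-9:
                    raise ValueError(f"frequencies at {locus} sum to {s}, not 1")
        if any(n < 0 for n in self.n_typed.values()):
            raise ValueError("n_typed must be >= 0")

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)

    def na(self, locus: str) -> int:
        """Number of alleles observed (p > 0) at a locus."""
        return sum(1 for p in self.freqs[locus].values() if p > 0)

    def p(self, locus: str, allele: int) -> float:
        return self.freqs.get(locus, {}).get(allele, 0.0)


@dataclass
class SampleMetadata:
    """Field record for one individual."""

    individual: str
    phenotype_label: str
    site: str = ""
    region: str = ""
    T_L: float | None = None  # total length, mm
    F_L: float | None = None  # fork length, mm
    W_t: float | None = None  # wet weight, g
    mtdna_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("T_L", "F_L", "W_t"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass
class SequenceAlignment:
    """Aligned nucleotide sequences over the alphabet {A, C, G, T, N, -}."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        lengths = {rid: len(s) for rid, s in self.records.items()}
        distinct = set(lengths.values())
        if len(distinct) != 1:
            counts: dict[int, int] = {}
            for l in lengths.values():
                counts[l] = counts.get(l, 0) + 1
            majority = max(counts, key=lambda l: counts[l])
            bad = [rid for rid, l in lengths.items() if l != majority]
            raise ValueError(f"ragged alignment; offending IDs: {bad}")
        if next(iter(distinct)) == 0:
            raise ValueError("alignment length must be > 0")
        self.records = {rid: s.upper() for rid, s in self.records.items()}

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, ids: Iterable[str]) -> "SequenceAlignment":
        return SequenceAlignment({rid: self.records[rid] for rid in ids})


# ---------------------------------------------------------------------------
# GenePop dialect
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genotypes_genepop(path: str) -> GenotypeMatrix:
    """Read a GenePop text file (2- or 3-digit diploid allele codes).

    The first line is a title and is ignored; locus names follow, one per
    line or comma-separated on a single line, until the first ``Pop``
    marker. Each ``Pop`` block becomes one group, labelled by the name of
    its first individual. Codes ``00``/``000`` denote a missing allele;
    a half-missing genotype is stored as fully missing.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenotypeParseError("empty file")
    # locus names
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not loci:
        raise GenotypeParseError("no locus names before first Pop")
    if i >= len(lines):
        raise GenotypeParseError("no Pop block found")

    individuals: list[str] = []
    group_of: dict[str, str] = {}
    rows: list[np.ndarray] = []
    width: int | None = None
    current_group: str | None = None

    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if not line.strip():
            continue
        if _POP_RE.match(line):
            current_group = None
            continue
        if "," not in line:
            raise GenotypeParseError(
                f"line {lineno + 1}: expected 'name , genotypes'"
            )
        name, _, geno = line.partition(",")
        name = name.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenotypeParseError(
                f"line {lineno + 1}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        pair_row = np.zeros((len(loci), 2), dtype=np.int64)
        for j, tok in enumerate(tokens):
            if not tok.isdigit() or len(tok) not in (4, 6):
                raise GenotypeParseError(
                    f"line {lineno + 1}: malformed allele code {tok!r}"
                )
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise GenotypeParseError(
                    f"line {lineno + 1}: allele-code width {w} != {width}"
                )
            a, b = int(tok[:w]), int(tok[w:])
            if a == 0 or b == 0:
                a = b = MISSING
            pair_row[j] = (a, b)
        if name in group_of:
            raise GenotypeParseError(f"line {lineno + 1}: duplicate individual {name!r}")
        if current_group is None:
            current_group = name
        individuals.append(name)
        group_of[name] = current_group
        rows.append(pair_row)

    if not rows:
        raise GenotypeParseError("no individuals")
    return GenotypeMatrix(individuals, loci, np.stack(rows), group_of)


def write_genotypes_genepop(g: GenotypeMatrix, path: str, title: str = "hybridscan export") -> None:
    """Write a GenotypeMatrix as a GenePop file, one Pop block per group."""
    width = 3 if g.calls.max(initial=0) > 99 else 2
    if g.calls.max(initial=0) >= 10**width:
        raise ValueError("allele size too large for 3-digit GenePop codes")
    lines = [title]
    lines.extend(g.loci)
    by_group: dict[str, list[int]] = {}
    for idx, ind in enumerate(g.individuals):
        by_group.setdefault(g.group_of.get(ind, ""), []).append(idx)
    for members in by_group.values():
        lines.append("Pop")
        for idx in members:
            toks = []
            for j in range(g.n_loci):
                a, b = g.calls[idx, j]
                toks.append(f"{a:0{width}d}{b:0{width}d}")
            lines.append(f"{g.individuals[idx]} , " + " ".join(toks))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tabular genotype CSV (individual, group, locus, allele1, allele2)
# ---------------------------------------------------------------------------


def read_genotypes_csv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype={"individual": str, "group": str, "locus": str})
    required = {"individual", "group", "locus", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(f"genotype CSV needs columns {sorted(required)}")
    individuals = list(dict.fromkeys(df["individual"]))
    loci = list(dict.fromkeys(df["locus"]))
    calls = np.zeros((len(individuals), len(loci), 2), dtype=np.int64)
    ind_ix = {x: i for i, x in enumerate(individuals)}
    loc_ix = {x: j for j, x in enumerate(loci)}
    group_of: dict[str, str] = {}
    for row in df.itertuples(index=False):
        i, j = ind_ix[row.individual], loc_ix[row.locus]
        group_of.setdefault(row.individual, row.group)
        a1 = 0 if pd.isna(row.allele1) else int(row.allele1)
        a2 = 0 if pd.isna(row.allele2) else int(row.allele2)
        if a1 == 0 or a2 == 0:
            a1 = a2 = MISSING
        calls[i, j] = (a1, a2)
    return GenotypeMatrix(individuals, loci, calls, group_of)


def write_genotypes_csv(g: GenotypeMatrix, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual", "group", "locus", "allele1", "allele2"])
        for i, ind in enumerate(g.individuals):
            grp = g.group_of.get(ind, "")
            for j, locus in enumerate(g.loci):
                a, b = g.calls[i, j]
                if a == MISSING:
                    w.writerow([ind, grp, locus, "", ""])
                else:
                    w.writerow([ind, grp, locus, int(a), int(b)])


# ---------------------------------------------------------------------------
# FASTA and metadata
# ---------------------------------------------------------------------------


def read_fasta_alignment(path: str) -> SequenceAlignment:
    """Read an aligned FASTA; sequences are upper-cased and must be equal length."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
    return SequenceAlignment(records)


def write_fasta_alignment(aln: SequenceAlignment, path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq in aln.records.items():
            fh.write(f">{rid}\n")
            for k in range(0, len(seq), 70):
                fh.write(seq[k : k + 70] + "\n")


_META_COLS = ["individual", "phenotype_label", "site", "region", "T_L", "F_L", "W_t", "mtdna_id"]


def read_metadata_csv(path: str) -> dict[str, SampleMetadata]:
    df = pd.read_csv(path, dtype={"individual": str})
    out: dict[str, SampleMetadata] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        md = SampleMetadata(
            individual=str(d["individual"]),
            phenotype_label=str(d.get("phenotype_label", "")),
            site=str(d.get("site", "") or ""),
            region=str(d.get("region", "") or ""),
            T_L=None if pd.isna(d.get("T_L")) else float(d["T_L"]),
            F_L=None if pd.isna(d.get("F_L")) else float(d["F_L"]),
            W_t=None if pd.isna(d.get("W_t")) else float(d["W_t"]),
            mtdna_id=None if pd.isna(d.get("mtdna_id")) else str(d["mtdna_id"]),
        )
        out[md.individual] = md
    return out


def write_metadata_csv(meta: Mapping[str, SampleMetadata], path: str) -> None:
    rows = []
    for md in meta.values():
        rows.append(
            {
                "individual": md.individual,
                "phenotype_label": md.phenotype_label,
                "site": md.site,
                "region": md.region,
                "T_L": md.T_L,
                "F_L": md.F_L,
                "W_t": md.W_t,
                "mtdna_id": md.mtdna_id,
            }
        )
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(
    g: GenotypeMatrix, grouping: Mapping[str, str] | None = None
) -> dict[str, AlleleFrequencyTable]:
    """Tabulate per-group, per-locus allele relative frequencies.

    Each allele copy counts once; missing calls are excluded from the
    denominator. A locus with no typed individual in a group keeps an
    empty frequency map and ``n_typed == 0``.
    """
    grouping = dict(grouping) if grouping is not None else dict(g.group_of)
    members: dict[str, list[int]] = {}
    for i, ind in enumerate(g.individuals):
        members.setdefault(grouping.get(ind, ""), []).append(i)
    out: dict[str, AlleleFrequencyTable] = {}
    for label, idx in members.items():
        if not idx:
            raise ValueError(f"empty group {label!r}")
        freqs: dict[str, dict[int, float]] = {}
        n_typed: dict[str, int] = {}
        sub = g.calls[idx]
        for j, locus in enumerate(g.loci):
            pairs = sub[:, j, :]
            typed = pairs[pairs[:, 0] != MISSING]
            n_typed[locus] = len(typed)
            if len(typed) == 0:
                freqs[locus] = {}
                continue
            alleles, counts = np.unique(typed.ravel(), return_counts=True)
            total = counts.sum()
            freqs[locus] = {int(a): float(c) / total for a, c in zip(alleles, counts)}
        out[label] = AlleleFrequencyTable(group=label, freqs=freqs, n_typed=n_typed)
    return out
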