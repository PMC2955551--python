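"""Reading, writing and validating multi-allelic diploid genotype data.

Genotypes are unordered pairs of integer allele codes (microsatellite
fragment sizes or arbitrary integers) per individual per locus, with an
all-or-nothing missing convention per (individual, locus).  Two on-disk
formats are supported: the two-row-per-individual text layout used by the
Bayesian clustering ecosystem ("STRUCTURE format") and a flat CSV with one
row per individual and two columns per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: internal missing sentinel inside GenotypeMatrix.calls
MISSING = -1

#: conventional missing code in genotype text files
DEFAULT_MISSING_CODE = -9

METADATA_COLUMNS = ["sample_id", "population_label", "declared_group", "role"]


class GenotypeError(ValueError):
    """Invalid genotype data or metadata."""


class ParseError(GenotypeError):
    """Malformed genotype file; the message names the offending line."""


@dataclass(frozen=True)
class Locus:
    """A multi-allelic marker: a name plus the set of observed allele codes.

    Allele codes are opaque integers (typically fragment sizes); no
    repeat-unit arithmetic is ever applied to them.
    """

    name: str
    allele_codes: tuple[int, ...]

    def __post_init__(self) -> None:
        codes = tuple(sorted(self.allele_codes))
        if len(codes) == 0:
            raise GenotypeError(f"locus {self.name!r} has no observed alleles")
        if len(set(codes)) != len(codes):
            raise GenotypeError(f"locus {self.name!r} has duplicate allele codes")
        object.__setattr__(self, "allele_codes", codes)

    @property
    def n_alleles(self) -> int:
        return len(self.allele_codes)

    def index_of(self, code: int) -> int:
        return self.allele_codes.index(code)


@dataclass
class GenotypeMatrix:
    """Diploid multi-allelic genotype calls for N individuals at L loci.

    ``calls`` has shape (N, L, 2) holding allele codes, with both entries
    equal to :data:`MISSING` where the call is missing.  Genotypes are
    unordered; the stored order of the two copies carries no phase meaning.
    """

    individuals: list[str]
    loci: list[Locus]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, l = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, l, 2):
            raise GenotypeError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{n} individuals x {l} loci"
            )
        if len(set(self.individuals)) != n:
            raise GenotypeError("duplicate sample identifiers")
        miss = self.calls == MISSING
        if np.any(miss[..., 0] != miss[..., 1]):
            raise GenotypeError("missing calls must be all-or-nothing per (individual, locus)")
        for j, locus in enumerate(self.loci):
            col = self.calls[:, j, :]
            observed = col[col != MISSING]
            unknown = set(observed.tolist()) - set(locus.allele_codes)
            if unknown:
                raise GenotypeError(
                    f"locus {locus.name!r}: calls use unregistered allele codes {sorted(unknown)}"
                )

    # -- basic queries -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (N, L) array, True where the call is missing."""
        return self.calls[..., 0] == MISSING

    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    # -- construction and slicing --------------------------------------

    @classmethod
    def from_calls(
        cls,
        individuals: Sequence[str],
        locus_names: Sequence[str],
        calls: np.ndarray,
        missing_code: int = DEFAULT_MISSING_CODE,
    ) -> "GenotypeMatrix":
        """Build a matrix from raw calls, deriving each locus's allele set.

        ``calls`` uses ``missing_code`` for missing entries; allele codes are
        whatever distinct integers appear per locus.
        """
        calls = np.asarray(calls, dtype=np.int64).copy()
        calls[calls == missing_code] = MISSING
        loci = []
        for j, name in enumerate(locus_names):
            col = calls[:, j, :]
            observed = np.unique(col[col != MISSING])
            if observed.size == 0:
                raise GenotypeError(f"locus {name!r} has no non-missing calls")
            loci.append(Locus(str(name), tuple(int(a) for a in observed)))
        return cls(list(map(str, individuals)), loci, calls)

    def subset_loci(self, names: Sequence[str]) -> "GenotypeMatrix":
        index = {l.name: j for j, l in enumerate(self.loci)}
        missing = [n for n in names if n not in index]
        if missing:
            raise GenotypeError(f"unknown loci requested: {missing}")
        js = [index[n] for n in names]
        return GenotypeMatrix(
            list(self.individuals), [self.loci[j] for j in js], self.calls[:, js, :]
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.individuals)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise GenotypeError(f"unknown individuals requested: {missing}")
        rows = [index[s] for s in ids]
        calls = self.calls[rows]
        # allele sets are re-derived: a subset may lose alleles entirely
        raw = calls.copy()
        raw[raw == MISSING] = DEFAULT_MISSING_CODE
        return GenotypeMatrix.from_calls(list(ids), self.locus_names, raw)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if self.individuals != other.individuals or self.loci != other.loci:
            return False
        # genotypes are unordered pairs: compare sorted copies
        return bool(
            np.array_equal(np.sort(self.calls, axis=2), np.sort(other.calls, axis=2))
        )


@dataclass(frozen=True)
class StructureDialect:
    """Layout flags for the two-row-per-individual text format.

    The canonical dialect is tab-separated with a header row of locus names
    and, per individual row, a sample-id column and a population-label
    column before the genotype columns.
    """

    label_column: bool = True
    popdata_column: bool = True
    missing_code: int = DEFAULT_MISSING_CODE
    sep: str = "\t"
    header: bool = True


def read_structure_file(
    path: str | Path, dialect: StructureDialect = StructureDialect()
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a two-row-per-individual genotype file.

    Each individual occupies two consecutive rows, one allele copy per row.
    Returns the genotype matrix plus a metadata frame (sample_id,
    population_label, declared_group, role); role is ``reference`` where a
    population label is present, else ``query``.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ParseError(f"{path}: empty file")
    offset = 0
    locus_names: list[str] | None = None
    if dialect.header:
        locus_names = lines[0].split(dialect.sep)
        offset = 1
    body = lines[offset:]
    if len(body) % 2 != 0:
        raise ParseError(
            f"{path}: odd number of genotype rows ({len(body)}); "
            "each individual needs exactly two rows"
        )
    n_meta = int(dialect.label_column) + int(dialect.popdata_column)
    width = None
    rows: list[tuple[str, str, list[int]]] = []  # (sample_id, pop, alleles)
    for i, line in enumerate(body):
        lineno = i + offset + 1
        fields = line.split(dialect.sep)
        if width is None:
            width = len(fields)
            if width <= n_meta:
                raise ParseError(f"{path}:{lineno}: no genotype columns")
        elif len(fields) != width:
            raise ParseError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {width})"
            )
        sample = fields[0] if dialect.label_column else f"ind{(i // 2) + 1}"
        pop = fields[int(dialect.label_column)] if dialect.popdata_column else ""
        try:
            alleles = [int(tok) for tok in fields[n_meta:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: unparseable allele token ({exc})") from None
        rows.append((sample, pop, alleles))

    n_loci = width - n_meta
    if locus_names is None:
        locus_names = [f"locus{j + 1}" for j in range(n_loci)]
    elif len(locus_names) != n_loci:
        raise ParseError(
            f"{path}: header names {len(locus_names)} loci but rows carry {n_loci}"
        )
    individuals, pops = [], []
    calls = np.empty((len(body) // 2, n_loci, 2), dtype=np.int64)
    for i in range(0, len(rows), 2):
        (s1, p1, a1), (s2, p2, a2) = rows[i], rows[i + 1]
        if s1 != s2 or p1 != p2:
            raise ParseError(
                f"{path}: rows for individual {s1!r} disagree on label/population"
            )
        individuals.append(s1)
        pops.append(p1)
        calls[i // 2, :, 0] = a1
        calls[i // 2, :, 1] = a2
    # missing must be all-or-nothing across the two rows
    m1 = calls[..., 0] == dialect.missing_code
    m2 = calls[..., 1] == dialect.missing_code
    if np.any(m1 != m2):
        i, j = np.argwhere(m1 != m2)[0]
        raise ParseError(
            f"{path}: half-missing genotype for individual {individuals[i]!r} "
            f"at locus {locus_names[j]!r}"
        )
    g = GenotypeMatrix.from_calls(individuals, locus_names, calls, dialect.missing_code)
    meta = pd.DataFrame(
        {
            "sample_id": individuals,
            "population_label": [p if p else None for p in pops],
            "declared_group": [None] * len(individuals),
            "role": ["reference" if p else "query" for p in pops],
        }
    )
    return g, meta


def write_structure_file(
    path: str | Path,
    g: GenotypeMatrix,
    metadata: pd.DataFrame | None = None,
    dialect: StructureDialect = StructureDialect(),
) -> None:
    """Write ``g`` in the two-row-per-individual text format."""
    path = Path(path)
    pops: Mapping[str, str] = {}
    if metadata is not None:
        pops = dict(
            zip(metadata["sample_id"], metadata["population_label"].fillna(""))
        )
    out: list[str] = []
    if dialect.header:
        out.append(dialect.sep.join(g.locus_names))
    calls = g.calls.copy()
    calls[calls == MISSING] = dialect.missing_code
    for i, sample in enumerate(g.individuals):
        for copy in (0, 1):
            fields: list[str] = []
            if dialect.label_column:
                fields.append(sample)
            if dialect.popdata_column:
                fields.append(str(pops.get(sample, "")))
            fields.extend(str(int(a)) for a in calls[i, :, copy])
            out.append(dialect.sep.join(fields))
    path.write_text("\n".join(out) + "\n")


def read_genotype_csv(
    path: str | Path,
    missing_code: int = DEFAULT_MISSING_CODE,
    panel: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a one-row-per-individual CSV: sample_id, population_label, then
    two columns per locus named ``<locus>.1`` / ``<locus>.2``.

    ``panel``, when given, is the expected locus list; a mismatch between it
    and the header raises :class:`GenotypeError`.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 4:
        raise ParseError(f"{path}: too few columns for a genotype CSV")
    cols = list(df.columns)
    if cols[0] != "sample_id" or cols[1] != "population_label":
        raise ParseError(
            f"{path}: first two columns must be sample_id, population_label"
        )
    geno_cols = cols[2:]
    if len(geno_cols) % 2 != 0:
        raise ParseError(f"{path}: genotype columns must come in pairs")
    locus_names = []
    for a, b in zip(geno_cols[::2], geno_cols[1::2]):
        base_a, base_b = a.rsplit(".", 1)[0], b.rsplit(".", 1)[0]
        if base_a != base_b:
            raise ParseError(f"{path}: column pair {a!r}/{b!r} names two loci")
        locus_names.append(base_a)
    if panel is not None and list(panel) != locus_names:
        raise GenotypeError(
            f"{path}: locus columns {locus_names} do not match the supplied panel"
        )
    calls = df[geno_cols].to_numpy(dtype=np.int64).reshape(len(df), -1, 2)
    g = GenotypeMatrix.from_calls(
        df["sample_id"].astype(str).tolist(), locus_names, calls, missing_code
    )
    pops = df["population_label"].astype(object).where(df["population_label"].notna(), None)
    meta = pd.DataFrame(
        {
            "sample_id": g.individuals,
            "population_label": list(pops),
            "declared_group": [None] * len(df),
            "role": ["reference" if p else "query" for p in pops],
        }
    )
    return g, meta


def write_genotype_csv(
    path: str | Path,
    g: GenotypeMatrix,
    metadata: pd.DataFrame | None = None,
    missing_code: int = DEFAULT_MISSING_CODE,
) -> None:
    pops: Mapping[str, str] = {}
    if metadata is not None:
        pops = dict(zip(metadata["sample_id"], metadata["population_label"].fillna("")))
    calls = g.calls.copy()
    calls[calls == MISSING] = missing_code
    data: dict[str, object] = {
        "sample_id": g.individuals,
        "population_label": [pops.get(s, "") for s in g.individuals],
    }
    for j, name in enumerate(g.locus_names):
        data[f"{name}.1"] = calls[:, j, 0]
        data[f"{name}.2"] = calls[:, j, 1]
    pd.DataFrame(data).to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample metadata CSV (sample_id, population_label,
    declared_group, role)."""
    meta = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise GenotypeError(f"{path}: metadata lacks columns {missing_cols}")
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise GenotypeError(f"duplicate sample_id {dup!r} in metadata")
    bad_role = set(meta["role"]) - {"reference", "query"}
    if bad_role:
        raise GenotypeError(f"unknown roles {sorted(bad_role)}; expected reference/query")
    refs = meta[meta["role"] == "reference"]
    unlabeled = refs["population_label"].isna() | (refs["population_label"] == "")
    if unlabeled.any():
        sid = refs.loc[unlabeled, "sample_id"].iloc[0]
        raise GenotypeError(f"reference sample {sid!r} lacks a population_label")
    return meta


def grouping_from_metadata(meta: pd.DataFrame, role: str = "reference") -> dict[str, list[str]]:
    """Partition sample ids by population_label (reference samples by default)."""
    sub = meta[meta["role"] == role] if role else meta
    grouping: dict[str, list[str]] = {}
    for pop, block in sub.groupby("population_label", sort=True):
        grouping[str(pop)] = block["sample_id"].tolist()
    return grouping


# ---------------------------------------------------------------------------
# allele counts


@dataclass
class AlleleCounts:
    """Per-population allele-copy and heterozygote tallies.

    ``counts[p, l, u]`` is the number of gene copies of allele ``u`` (index
    into ``loci[l].allele_codes``) observed in population ``p`` at locus
    ``l``; ``het[p, l, u]`` the number of individuals heterozygous *for*
    allele ``u`` (carrying exactly one copy); ``n[p, l]`` the non-missing
    sample size.  ``A_max`` columns beyond a locus's allele count are zero.
    """

    populations: list[str]
    loci: list[Locus]
    counts: np.ndarray  # (P, L, A_max) int
    het: np.ndarray  # (P, L, A_max) int
    n: np.ndarray  # (P, L) int

    @property
    def het_total(self) -> np.ndarray:
        """(P, L) count of heterozygous individuals (two distinct alleles)."""
        return self.het.sum(axis=2) // 2

    def frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Sample allele frequencies p̃ and per-allele heterozygote
        frequencies h̃, shape (P, L, A_max); zero where n = 0."""
        denom = np.where(self.n > 0, self.n, 1)[:, :, None]
        p = self.counts / (2.0 * denom)
        h = self.het / (1.0 * denom)
        return p, h


def allele_counts(
    g: GenotypeMatrix, grouping: Mapping[str, Sequence[str]]
) -> AlleleCounts:
    """Tally allele copies and heterozygotes per (population, locus, allele).

    ``grouping`` maps population name to the sample ids it contains; it may
    cover a subset of the matrix.  Missing calls are excluded per locus, so
    allele-copy counts sum to 2 x non-missing individuals at each
    (population, locus).
    """
    pops = sorted(grouping)
    index = {s: i for i, s in enumerate(g.individuals)}
    a_max = max(l.n_alleles for l in g.loci)
    P, L = len(pops), g.n_loci
    counts = np.zeros((P, L, a_max), dtype=np.int64)
    het = np.zeros((P, L, a_max), dtype=np.int64)
    n = np.zeros((P, L), dtype=np.int64)

    # allele code -> per-locus index lookup
    code_maps = [
        {code: u for u, code in enumerate(l.allele_codes)} for l in g.loci
    ]
    for p_i, pop in enumerate(pops):
        members = grouping[pop]
        if len(members) == 0:
            raise GenotypeError(f"population {pop!r} is empty")
        unknown = [s for s in members if s not in index]
        if unknown:
            raise GenotypeError(f"population {pop!r} lists unknown samples {unknown}")
        rows = [index[s] for s in members]
        calls = g.calls[rows]  # (m, L, 2)
        valid = calls[..., 0] != MISSING
        n[p_i] = valid.sum(axis=0)
        for l in range(L):
            cmap = code_maps[l]
            sub = calls[valid[:, l], l, :]
            for a1, a2 in sub:
                u1, u2 = cmap[int(a1)], cmap[int(a2)]
                counts[p_i, l, u1] += 1
                counts[p_i, l, u2] += 1
                if u1 != u2:
                    het[p_i, l, u1] += 1
                    het[p_i, l, u2] += 1
    return AlleleCounts(pops, list(g.loci), counts, het, n)
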