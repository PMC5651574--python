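"""Readers and writers for genotype matrices, metadata tables and trees.

Canonical on-disk dialects are plain text: PLINK ``.ped``/``.map`` pairs and a
TSV genotype matrix (rows = samples, columns = loci, calls coded ``AA``/``AB``/
``BB`` or two allele letters), TSV tables for SNP metadata, sample→breed maps
and gene annotations, square labelled TSV distance matrices, and Newick trees.

Genotypes are held as B-allele dosage codes: 0, 1 or 2 copies of the B allele,
with ``MISSING`` (−1) marking no-calls.  When allele metadata is absent the
lexicographically later allele observed at a locus is taken as B, which makes
the coding deterministic without a chip manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MISSING = -1

#: genotype strings accepted as a missing call (PLINK and GenomeStudio exports)
MISSING_CODES = frozenset({"NA", "--", "00", "0 0", "NC", "", "nan"})


class FormatError(ValueError):
    """Malformed input file (wrong shape, bad token); names the offending line."""


class ValidationError(ValueError):
    """Structurally parseable input violating a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """N samples × M loci matrix of B-allele dosage codes.

    ``dosage`` is an ``int8`` array with entries in {0, 1, 2} or ``MISSING``.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.locus_ids = list(self.locus_ids)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = len(self.sample_ids), len(self.locus_ids)
        if self.dosage.shape != (n, m):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != (samples={n}, loci={m})"
            )
        for name, ids in (("sample", self.sample_ids), ("locus", self.locus_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {name} ids")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid dosage code {self.dosage[i, j]} at "
                f"({self.sample_ids[i]}, {self.locus_ids[j]})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (N, M) array, True where the call is missing."""
        return self.dosage == MISSING

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(sample_ids)
        return GenotypeMatrix(list(sample_ids), self.locus_ids, self.dosage[idx])

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {l: j for j, l in enumerate(self.locus_ids)}
        try:
            idx = np.array([pos[l] for l in locus_ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown locus id {exc.args[0]!r}") from None
        return GenotypeMatrix(self.sample_ids, list(locus_ids), self.dosage[:, idx])


@dataclass
class SnpRecord:
    """Per-SNP array metadata (position is 1-based on the reference build)."""

    locus_id: str
    chromosome: str
    position_bp: int
    allele_a: str = "A"
    allele_b: str = "B"
    gentrain_score: float | None = None
    mapping_hits: int | None = None

    def __post_init__(self) -> None:
        self.position_bp = int(self.position_bp)
        if self.position_bp < 1:
            raise ValidationError(f"{self.locus_id}: position {self.position_bp} < 1")
        if self.gentrain_score is not None and not 0.0 <= self.gentrain_score <= 1.0:
            raise ValidationError(
                f"{self.locus_id}: GenTrain score {self.gentrain_score} outside [0, 1]"
            )
        if self.mapping_hits is not None and self.mapping_hits < 0:
            raise ValidationError(f"{self.locus_id}: negative mapping hit count")


@dataclass
class SampleRecord:
    sample_id: str
    breed: str
    site: str | None = None

    def __post_init__(self) -> None:
        if not self.breed:
            raise ValidationError(f"{self.sample_id}: empty breed label")


@dataclass
class GeneRecord:
    """Protein-coding gene span, 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        self.start_bp, self.end_bp = int(self.start_bp), int(self.end_bp)
        if not 1 <= self.start_bp <= self.end_bp:
            raise ValidationError(
                f"{self.gene_id}: invalid span [{self.start_bp}, {self.end_bp}]"
            )


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal over labelled units."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise ValidationError(f"values shape {self.values.shape} != ({n}, {n})")
        finite = np.isfinite(self.values)
        both = finite & finite.T
        if not np.allclose(
            self.values[both], self.values.T[both], atol=1e-9, rtol=0.0
        ) or not (finite == finite.T).all():
            raise ValidationError("distance matrix not symmetric within 1e-9")
        if (np.diagonal(self.values) != 0).any():
            raise ValidationError("distance matrix diagonal must be exactly 0")
        if (self.values[finite] < 0).any():
            raise ValidationError("negative distances")
        # enforce exact symmetry so downstream condensed forms are unambiguous
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)


# ---------------------------------------------------------------------------
# genotype IO
# ---------------------------------------------------------------------------


def _b_allele(observed: set[str], record: SnpRecord | None) -> tuple[str, str]:
    """Return (allele_a, allele_b) for a locus.

    Metadata wins; otherwise B is the lexicographically later observed allele.
    A locus with a single observed allele is coded as all A (dosage 0).
    """
    if record is not None and {record.allele_a, record.allele_b} >= observed:
        return record.allele_a, record.allele_b
    alleles = sorted(observed)
    if len(alleles) > 2:
        raise FormatError(f"more than two alleles observed: {alleles}")
    if len(alleles) == 2:
        return alleles[0], alleles[1]
    if len(alleles) == 1:
        return alleles[0], "B" if alleles[0] != "B" else "Z"
    return "A", "B"


def read_genotypes(
    path: str | Path,
    format: str = "tsv_matrix",
    snps: Sequence[SnpRecord] | None = None,
) -> tuple[GenotypeMatrix, list[SnpRecord]]:
    """Read a genotype matrix; returns the matrix and per-locus SNP records.

    ``format="ped_map"`` expects ``path`` to be the PLINK prefix (or the
    ``.ped`` file); ``format="tsv_matrix"`` a TSV with a header of locus ids
    and one row per sample.  Unparseable calls become missing only when they
    match a known missing code; anything else is a format error.
    """
    if format == "ped_map":
        return _read_ped_map(Path(path), snps)
    if format == "tsv_matrix":
        return _read_tsv_matrix(Path(path), snps)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_ped_map(path: Path, snps: Sequence[SnpRecord] | None):
    prefix = path.with_suffix("") if path.suffix in {".ped", ".map"} else path
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    map_records: list[tuple[str, str, int]] = []
    for ln, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
        chrom, locus_id, _cm, pos = parts[:4]
        map_records.append((locus_id, chrom, int(pos)))
    m = len(map_records)
    meta = {r.locus_id: r for r in snps} if snps else {}

    sample_ids: list[str] = []
    calls: list[list[tuple[str, str]]] = []
    for ln, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise FormatError(
                f"{ped_path}:{ln}: expected {6 + 2 * m} fields for {m} mapped "
                f"loci, got {len(parts)}"
            )
        sample_ids.append(parts[1])
        alleles = parts[6:]
        calls.append(
            [(alleles[2 * j], alleles[2 * j + 1]) for j in range(m)]
        )

    n = len(sample_ids)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    out_snps: list[SnpRecord] = []
    for j, (locus_id, chrom, pos) in enumerate(map_records):
        observed = {a for row in calls for a in row[j] if a != "0"}
        a_allele, b_allele = _b_allele(observed, meta.get(locus_id))
        for i in range(n):
            a1, a2 = calls[i][j]
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = (a1 == b_allele) + (a2 == b_allele)
        rec = meta.get(locus_id)
        if rec is None:
            rec = SnpRecord(locus_id, chrom, pos, a_allele, b_allele)
        out_snps.append(rec)
    return GenotypeMatrix(sample_ids, [r[0] for r in map_records], dosage), out_snps


def _read_tsv_matrix(path: Path, snps: Sequence[SnpRecord] | None):
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file (header row required)")
    header = lines[0].rstrip("\n").split("\t")
    locus_ids = header[1:]
    if len(set(locus_ids)) != len(locus_ids):
        raise ValidationError(f"{path}: duplicate locus ids in header")
    meta = {r.locus_id: r for r in snps} if snps else {}

    sample_ids: list[str] = []
    raw_rows: list[list[str]] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise FormatError(
                f"{path}:{ln}: expected {len(header)} columns, got {len(parts)}"
            )
        sample_ids.append(parts[0])
        raw_rows.append(parts[1:])

    n, m = len(sample_ids), len(locus_ids)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    out_snps: list[SnpRecord] = []
    for j, locus_id in enumerate(locus_ids):
        col = [row[j].strip() for row in raw_rows]
        observed = {a for g in col if g not in MISSING_CODES for a in g if a != "0"}
        a_allele, b_allele = _b_allele(observed, meta.get(locus_id))
        for i, g in enumerate(col):
            if g in MISSING_CODES:
                continue
            if len(g) != 2 or any(a not in (a_allele, b_allele) for a in g):
                raise FormatError(
                    f"{path}: row {i + 2}: unparseable genotype {g!r} at {locus_id}"
                )
            dosage[i, j] = sum(a == b_allele for a in g)
        rec = meta.get(locus_id)
        if rec is None:
            rec = SnpRecord(locus_id, "0", 1, a_allele, b_allele)
        out_snps.append(rec)
    return GenotypeMatrix(sample_ids, locus_ids, dosage), out_snps


def write_genotypes(
    gm: GenotypeMatrix,
    path: str | Path,
    format: str = "tsv_matrix",
    snps: Sequence[SnpRecord] | None = None,
) -> None:
    """Write a genotype matrix in the requested dialect (round-trip safe)."""
    meta = {r.locus_id: r for r in snps} if snps else {}
    path = Path(path)
    if format == "tsv_matrix":
        code = {0: "AA", 1: "AB", 2: "BB", MISSING: "NA"}
        codes_per_locus = []
        for locus_id in gm.locus_ids:
            rec = meta.get(locus_id)
            if rec is not None:
                a, b = rec.allele_a, rec.allele_b
                # sort within the call so heterozygotes are written canonically
                aa, ab, bb = a + a, "".join(sorted(a + b)), b + b
                codes_per_locus.append({0: aa, 1: ab, 2: bb, MISSING: "NA"})
            else:
                codes_per_locus.append(code)
        with path.open("w") as fh:
            fh.write("sample_id\t" + "\t".join(gm.locus_ids) + "\n")
            for i, sid in enumerate(gm.sample_ids):
                row = [codes_per_locus[j][int(gm.dosage[i, j])] for j in range(gm.n_loci)]
                fh.write(sid + "\t" + "\t".join(row) + "\n")
        return
    if format == "ped_map":
        prefix = path.with_suffix("") if path.suffix in {".ped", ".map"} else path
        with prefix.with_suffix(".map").open("w") as fh:
            for locus_id in gm.locus_ids:
                rec = meta.get(locus_id, SnpRecord(locus_id, "0", 1))
                fh.write(f"{rec.chromosome}\t{locus_id}\t0\t{rec.position_bp}\n")
        with prefix.with_suffix(".ped").open("w") as fh:
            for i, sid in enumerate(gm.sample_ids):
                fields = ["FAM", sid, "0", "0", "0", "-9"]
                for j, locus_id in enumerate(gm.locus_ids):
                    rec = meta.get(locus_id, SnpRecord(locus_id, "0", 1))
                    a, b = rec.allele_a, rec.allele_b
                    d = int(gm.dosage[i, j])
                    pair = {0: (a, a), 1: (a, b), 2: (b, b), MISSING: ("0", "0")}[d]
                    fields.extend(pair)
                fh.write(" ".join(fields) + "\n")
        return
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# metadata tables
# ---------------------------------------------------------------------------


def _read_table(path: Path, required: Sequence[str]) -> list[dict[str, str]]:
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise FormatError(
                f"{path}:{ln}: expected {len(header)} columns, got {len(parts)}"
            )
        rows.append(dict(zip(header, parts)))
    return rows


def read_sample_map(path: str | Path) -> list[SampleRecord]:
    rows = _read_table(Path(path), ["sample_id", "breed"])
    records = [
        SampleRecord(r["sample_id"], r["breed"], r.get("site") or None) for r in rows
    ]
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sample ids")
    return records


def write_sample_map(records: Iterable[SampleRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tbreed\tsite\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.breed}\t{r.site or ''}\n")


def read_gene_annotation(path: str | Path) -> list[GeneRecord]:
    rows = _read_table(Path(path), ["gene_id", "chromosome", "start_bp", "end_bp"])
    return [
        GeneRecord(r["gene_id"], r["chromosome"], int(r["start_bp"]), int(r["end_bp"]))
        for r in rows
    ]


def write_gene_annotation(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tchromosome\tstart_bp\tend_bp\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chromosome}\t{g.start_bp}\t{g.end_bp}\n")


_SNP_COLUMNS = [
    "locus_id",
    "chromosome",
    "position_bp",
    "allele_a",
    "allele_b",
    "gentrain_score",
    "mapping_hits",
]


def read_snp_metadata(path: str | Path) -> list[SnpRecord]:
    rows = _read_table(Path(path), ["locus_id", "chromosome", "position_bp"])
    out = []
    for r in rows:
        gentrain = r.get("gentrain_score", "")
        hits = r.get("mapping_hits", "")
        out.append(
            SnpRecord(
                r["locus_id"],
                r["chromosome"],
                int(r["position_bp"]),
                r.get("allele_a", "A") or "A",
                r.get("allele_b", "B") or "B",
                float(gentrain) if gentrain not in ("", "NA") else None,
                int(hits) if hits not in ("", "NA") else None,
            )
        )
    return out


def write_snp_metadata(snps: Iterable[SnpRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_SNP_COLUMNS) + "\n")
        for s in snps:
            gentrain = "" if s.gentrain_score is None else f"{s.gentrain_score:.6g}"
            hits = "" if s.mapping_hits is None else str(s.mapping_hits)
            fh.write(
                f"{s.locus_id}\t{s.chromosome}\t{s.position_bp}\t{s.allele_a}\t"
                f"{s.allele_b}\t{gentrain}\t{hits}\n"
            )


# ---------------------------------------------------------------------------
# distance matrices and trees
# ---------------------------------------------------------------------------


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t" + "\t".join(dm.labels) + "\n")
        for i, label in enumerate(dm.labels):
            row = "\t".join(f"{v:.12g}" for v in dm.values[i])
            fh.write(f"{label}\t{row}\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    labels = lines[0].split("\t")[1:]
    values = np.zeros((len(labels), len(labels)))
    if len(lines) - 1 != len(labels):
        raise FormatError(
            f"{path}: {len(labels)} labels but {len(lines) - 1} data rows"
        )
    for i, line in enumerate(lines[1:]):
        parts = line.split("\t")
        if parts[0] != labels[i]:
            raise FormatError(f"{path}: row label {parts[0]!r} != {labels[i]!r}")
        if len(parts) != len(labels) + 1:
            raise FormatError(f"{path}: row {i + 2} has {len(parts) - 1} values")
        values[i] = [float(v) for v in parts[1:]]
    return DistanceMatrix(labels, values)


def write_newick(newick: str, path: str | Path) -> None:
    newick = newick.strip()
    if not newick.endswith(";"):
        newick += ";"
    Path(path).write_text(newick + "\n")


def as_dict(obj) -> dict:
    """Dataclass → plain dict (for JSON reports)."""
    return dataclasses.asdict(obj)
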