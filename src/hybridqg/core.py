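"""Core data containers and on-disk formats shared across the package.

All tabular artifacts are plain TSV so that runs are diffable and
reproducible; relationship matrices carry a JSON sidecar with their kind.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = np.nan


class ConfigurationError(ValueError):
    """Invalid parameters or an infeasible request."""


class DataError(ValueError):
    """Input data violate a precondition of the operation."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions on a genetic (centimorgan) map.

    Parameters
    ----------
    chromosome : array of str, one label per marker (e.g. ``A01`` .. ``C09``).
    marker_id : array of unique marker names.
    position_cm : array of non-negative map positions, non-decreasing within
        each chromosome.
    """

    chromosome: np.ndarray
    marker_id: np.ndarray
    position_cm: np.ndarray

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chromosome, dtype=object)
        mid = np.asarray(self.marker_id, dtype=object)
        pos = np.asarray(self.position_cm, dtype=float)
        if not (len(chrom) == len(mid) == len(pos)):
            raise ConfigurationError("map columns must have equal length")
        if len(set(mid)) != len(mid):
            raise ConfigurationError("duplicate marker ids in map")
        if np.any(pos < 0):
            raise ConfigurationError("negative map positions")
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) < 0):
                raise ConfigurationError(f"positions decrease within chromosome {c}")
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "position_cm", pos)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def chromosomes(self) -> list:
        return list(pd.unique(self.chromosome))

    def subset(self, idx: np.ndarray) -> "GeneticMap":
        return GeneticMap(self.chromosome[idx], self.marker_id[idx], self.position_cm[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "cM": self.position_cm,
            }
        )


def default_map(
    n_chromosomes: int = 19,
    chrom_length_cm: float = 80.0,
    markers_per_chrom: int = 80,
) -> GeneticMap:
    """Evenly spaced default genome: 19 chromosomes x 80 markers (~1,520 loci).

    Chromosome labels follow the A01..A10 / C01..C09 convention up to 19
    chromosomes, then continue as D01, D02, ...
    """
    labels = [f"A{i:02d}" for i in range(1, 11)] + [f"C{i:02d}" for i in range(1, 10)]
    while len(labels) < n_chromosomes:
        labels.append(f"D{len(labels) - 18:02d}")
    chroms, mids, pos = [], [], []
    for c in range(n_chromosomes):
        lab = labels[c]
        p = np.linspace(0.0, chrom_length_cm, markers_per_chrom)
        for j in range(markers_per_chrom):
            chroms.append(lab)
            mids.append(f"{lab}_m{j + 1:04d}")
        pos.extend(p.tolist())
    return GeneticMap(np.array(chroms, dtype=object), np.array(mids, dtype=object), np.array(pos))


# ---------------------------------------------------------------------------
# Marker matrix
# ---------------------------------------------------------------------------

GROUP_INBRED = "inbred"
GROUP_HYBRID = "hybrid"


@dataclass
class MarkerMatrix:
    """Coded biallelic genotypes: individuals x markers.

    Codes: -1 (homozygote bb), 0 (heterozygote), +1 (homozygote AA),
    NaN (missing).  ``group`` labels each individual as ``inbred`` or
    ``hybrid``; inbred rows must contain no heterozygote codes.
    """

    codes: np.ndarray
    map: GeneticMap
    individual_ids: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.group = np.asarray(self.group, dtype=object)
        n, m = self.codes.shape
        if m != self.map.n_markers:
            raise DataError("codes/map dimension mismatch")
        if n != len(self.individual_ids) or n != len(self.group):
            raise DataError("codes/ids dimension mismatch")
        if len(set(self.individual_ids)) != n:
            raise DataError("duplicate individual ids")
        bad = set(np.unique(self.codes[~np.isnan(self.codes)])) - {-1.0, 0.0, 1.0}
        if bad:
            raise DataError(f"invalid genotype codes: {sorted(bad)}")
        inbred = self.group == GROUP_INBRED
        if inbred.any():
            het = np.nansum(self.codes[inbred] == 0)
            if het:
                raise DataError("inbred rows contain heterozygote codes")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def subset_markers(self, idx: np.ndarray) -> "MarkerMatrix":
        return MarkerMatrix(self.codes[:, idx], self.map.subset(idx), self.individual_ids, self.group)

    def subset_individuals(self, idx: np.ndarray) -> "MarkerMatrix":
        return MarkerMatrix(self.codes[idx], self.map, self.individual_ids[idx], self.group[idx])

    def concat(self, other: "MarkerMatrix") -> "MarkerMatrix":
        if not np.array_equal(self.map.marker_id, other.map.marker_id):
            raise DataError("marker panels differ")
        return MarkerMatrix(
            np.vstack([self.codes, other.codes]),
            self.map,
            np.concatenate([self.individual_ids, other.individual_ids]),
            np.concatenate([self.group, other.group]),
        )


def write_genotype_tsv(markers: MarkerMatrix, path: str | Path) -> None:
    """Genotype TSV dialect: rows = markers, first three columns
    marker_id/chromosome/cM, then one column per individual; missing = NA.
    A ``#group`` comment line records inbred/hybrid labels."""
    codes = markers.codes.T
    cols = {
        iid: [("NA" if np.isnan(v) else str(int(v))) for v in codes[:, j]]
        for j, iid in enumerate(markers.individual_ids)
    }
    df = pd.concat([markers.map.to_frame(), pd.DataFrame(cols)], axis=1)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#group\t" + "\t".join(str(g) for g in markers.group) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> MarkerMatrix:
    path = Path(path)
    group_line = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#group"):
            group_line = first.rstrip("\n").split("\t")[1:]
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    meta_cols = ["marker_id", "chromosome", "cM"]
    if df.columns[:3].tolist() != meta_cols:
        raise DataError(f"genotype TSV must start with columns {meta_cols}")
    gmap = GeneticMap(
        df["chromosome"].to_numpy(dtype=object),
        df["marker_id"].to_numpy(dtype=object),
        df["cM"].to_numpy(dtype=float),
    )
    ind_cols = df.columns[3:]
    codes = df[ind_cols].replace("NA", np.nan).to_numpy(dtype=float).T
    if group_line is None:
        # without labels, infer: any heterozygote -> hybrid
        group = np.array(
            [GROUP_HYBRID if np.any(codes[i] == 0) else GROUP_INBRED for i in range(len(ind_cols))],
            dtype=object,
        )
    else:
        group = np.array(group_line, dtype=object)
    return MarkerMatrix(codes, gmap, ind_cols.to_numpy(dtype=object), group)


# ---------------------------------------------------------------------------
# Crossing design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossingDesign:
    """Unordered parent pairs (ids), no selfs, no duplicates."""

    crosses: tuple

    def __post_init__(self) -> None:
        seen = set()
        for p, q in self.crosses:
            if p == q:
                raise ConfigurationError(f"self-cross {p} x {q}")
            key = frozenset((p, q))
            if key in seen:
                raise ConfigurationError(f"duplicate cross {p} x {q}")
            seen.add(key)

    @property
    def n_crosses(self) -> int:
        return len(self.crosses)

    def hybrid_id(self, i: int) -> str:
        p, q = self.crosses[i]
        return f"{p}x{q}"

    def parents_of(self) -> dict:
        return {self.hybrid_id(i): self.crosses[i] for i in range(self.n_crosses)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hybrid_id": [self.hybrid_id(i) for i in range(self.n_crosses)],
                "parent1": [p for p, _ in self.crosses],
                "parent2": [q for _, q in self.crosses],
            }
        )


def write_crosses_tsv(design: CrossingDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_crosses_tsv(path: str | Path) -> CrossingDesign:
    df = pd.read_csv(path, sep="\t")
    return CrossingDesign(tuple(zip(df["parent1"].astype(str), df["parent2"].astype(str))))


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

STAGE_PLOT = "plot"
STAGE_WITHIN = "within_env_means"
STAGE_ACROSS = "across_env_means"


@dataclass
class PhenotypeTable:
    """Plot-level records or derived adjusted means.

    ``records`` columns: genotype_id, environment, replicate, value.
    For means stages, environment is the environment label (within stage)
    or ``ALL`` (across stage) and replicate is 1.
    """

    records: pd.DataFrame
    stage: str = STAGE_PLOT

    def __post_init__(self) -> None:
        required = ["genotype_id", "environment", "replicate", "value"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise DataError(f"phenotype table missing columns {missing}")
        if self.stage not in (STAGE_PLOT, STAGE_WITHIN, STAGE_ACROSS):
            raise DataError(f"unknown stage {self.stage!r}")
        vals = self.records["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise DataError("non-finite phenotype values")
        keys = self.records[["genotype_id", "environment", "replicate"]]
        if keys.duplicated().any():
            raise DataError("duplicate (genotype, environment, replicate) keys")

    @property
    def genotype_ids(self) -> np.ndarray:
        return pd.unique(self.records["genotype_id"])

    @property
    def environments(self) -> np.ndarray:
        return pd.unique(self.records["environment"])

    def values_for(self, genotype_ids: Sequence) -> np.ndarray:
        """Value per genotype id (means stages only, single env)."""
        piv = self.records.set_index("genotype_id")["value"]
        return piv.loc[list(genotype_ids)].to_numpy(dtype=float)


def write_phenotype_tsv(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.records.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotype_tsv(path: str | Path, stage: str = STAGE_PLOT) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    return PhenotypeTable(df, stage=stage)


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------

KIND_KINSHIP = "kinship"
KIND_ADDITIVE = "additive"
KIND_DOMINANCE = "dominance"
KIND_GAUSSIAN = "gaussian"


@dataclass
class RelationshipMatrix:
    """Symmetric PSD similarity among individuals."""

    values: np.ndarray
    kind: str
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise DataError("relationship matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataError("relationship matrix not symmetric")
        diag = np.diag(self.values)
        if not np.all(np.isfinite(diag)) or np.any(diag <= 0):
            raise DataError("relationship diagonal must be finite and positive")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def reindex(self, ids: Sequence) -> "RelationshipMatrix":
        lookup = {iid: i for i, iid in enumerate(self.individual_ids)}
        try:
            idx = np.array([lookup[i] for i in ids])
        except KeyError as e:
            raise DataError(f"individual {e.args[0]!r} absent from relationship matrix")
        return RelationshipMatrix(self.values[np.ix_(idx, idx)], self.kind, np.asarray(ids, dtype=object))

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values).min())


def write_relationship_tsv(rm: RelationshipMatrix, path: str | Path) -> None:
    df = pd.DataFrame(rm.values, index=rm.individual_ids, columns=rm.individual_ids)
    df.to_csv(path, sep="\t", index_label="id")
    Path(str(path) + ".json").write_text(json.dumps({"kind": rm.kind}))


def read_relationship_tsv(path: str | Path) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    kind = KIND_KINSHIP
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        kind = json.loads(sidecar.read_text()).get("kind", kind)
    return RelationshipMatrix(df.to_numpy(dtype=float), kind, df.columns.to_numpy(dtype=object))


# ---------------------------------------------------------------------------
# Design matrices (F-infinity metric)
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrices:
    """Additive (A in {-1,0,1}) and dominance (D in {0,1}) marker designs."""

    A: np.ndarray
    D: np.ndarray
    map: GeneticMap
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.A.shape != self.D.shape:
            raise DataError("A/D shape mismatch")
        if self.A.shape[1] != self.map.n_markers:
            raise DataError("design/map mismatch")
        if self.A.shape[0] != len(self.individual_ids):
            raise DataError("design/ids mismatch")

    @property
    def n_individuals(self) -> int:
        return self.A.shape[0]

    @property
    def n_markers(self) -> int:
        return self.A.shape[1]

    def reindex(self, ids: Sequence) -> "DesignMatrices":
        lookup = {iid: i for i, iid in enumerate(self.individual_ids)}
        idx = np.array([lookup[i] for i in ids])
        return DesignMatrices(self.A[idx], self.D[idx], self.map, np.asarray(ids, dtype=object))
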