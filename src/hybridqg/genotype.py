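"""Marker quality control, hybrid genotype inference and design matrices.

Genotypes are coded -1/0/+1 (homozygote, heterozygote, homozygote).  Hybrid
codes are fully determined by their two inbred parents.  Design matrices use
the F-infinity metric: the additive column equals the code, the dominance
column is the heterozygote indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CrossingDesign,
    DataError,
    DesignMatrices,
    GROUP_HYBRID,
    GROUP_INBRED,
    MarkerMatrix,
)


def infer_hybrid_genotypes(parents: MarkerMatrix, design: CrossingDesign) -> MarkerMatrix:
    """Hybrid code = mean of the two parental codes.

    (+1,+1) -> +1, (-1,-1) -> -1, (+1,-1) -> 0; missing in either parent
    propagates to missing.  Symmetric in parent order.
    """
    lookup = {iid: i for i, iid in enumerate(parents.individual_ids)}
    rows = []
    ids = []
    for k, (p, q) in enumerate(design.crosses):
        for parent in (p, q):
            if parent not in lookup:
                raise DataError(f"parent {parent!r} absent from marker matrix")
        cp, cq = parents.codes[lookup[p]], parents.codes[lookup[q]]
        for parent, c in ((p, cp), (q, cq)):
            het = np.where(c == 0)[0]
            if het.size:
                raise DataError(
                    f"parent {parent!r} heterozygous at marker "
                    f"{parents.map.marker_id[het[0]]!r}"
                )
        rows.append((cp + cq) / 2.0)
        ids.append(design.hybrid_id(k))
    codes = np.array(rows)
    group = np.full(len(ids), GROUP_HYBRID, dtype=object)
    return MarkerMatrix(codes, parents.map, np.array(ids, dtype=object), group)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def allele_frequency(codes: np.ndarray) -> np.ndarray:
    """Frequency of the +1 allele per marker, ignoring missing entries."""
    with np.errstate(invalid="ignore"):
        return (np.nanmean(codes, axis=0) + 1.0) / 2.0


def minor_allele_frequency(codes: np.ndarray) -> np.ndarray:
    p = allele_frequency(codes)
    return np.minimum(p, 1.0 - p)


@dataclass
class QcReport:
    n_input: int
    n_retained: int
    removed: pd.DataFrame  # marker_id, reason, statistic
    maf_min: float
    miss_max: float

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "maf_min": self.maf_min,
            "miss_max": self.miss_max,
            "removed": self.removed.to_dict(orient="records"),
        }


def qc_filter(
    markers: MarkerMatrix, maf_min: float = 0.05, miss_max: float = 0.05
) -> tuple:
    """Retain markers with MAF strictly > maf_min and missing fraction
    strictly < miss_max (both boundaries exclusive; ties, up to a 1e-12
    float tolerance, are removed)."""
    if not (0.0 <= maf_min <= 0.5):
        raise DataError("maf_min must be in [0, 0.5]")
    if not (0.0 <= miss_max <= 1.0):
        raise DataError("miss_max must be in [0, 1]")
    if markers.n_markers == 0 or markers.n_individuals == 0:
        raise DataError("empty marker matrix")
    miss = np.mean(np.isnan(markers.codes), axis=0)
    all_missing = miss >= 1.0
    maf = np.zeros(markers.n_markers)
    ok_cols = ~all_missing
    maf[ok_cols] = minor_allele_frequency(markers.codes[:, ok_cols])
    tol = 1e-12
    keep = (maf > maf_min + tol) & (miss < miss_max - tol) & ~all_missing
    removed = []
    for j in np.where(~keep)[0]:
        if all_missing[j]:
            removed.append((markers.map.marker_id[j], "all_missing", 1.0))
        elif miss[j] >= miss_max - tol:
            removed.append((markers.map.marker_id[j], "missingness", float(miss[j])))
        else:
            removed.append((markers.map.marker_id[j], "maf", float(maf[j])))
    report = QcReport(
        n_input=markers.n_markers,
        n_retained=int(keep.sum()),
        removed=pd.DataFrame(removed, columns=["marker_id", "reason", "statistic"]),
        maf_min=maf_min,
        miss_max=miss_max,
    )
    return markers.subset_markers(np.where(keep)[0]), report


def dedup_perfect_ld(markers: MarkerMatrix, tol: float = 1e-12) -> tuple:
    """Collapse within-chromosome marker clusters in perfect LD (r^2 = 1,
    including r = -1) to their map-first representative.

    Requires complete genotypes (impute or drop missing first).
    """
    if np.isnan(markers.codes).any():
        raise DataError("dedup_perfect_ld requires complete genotypes")
    codes = markers.codes
    n, m = codes.shape
    keep = np.ones(m, dtype=bool)
    clusters: dict = {}
    chrom = markers.map.chromosome
    sd = codes.std(axis=0)
    centered = codes - codes.mean(axis=0)
    for c in pd.unique(chrom):
        idx = np.where(chrom == c)[0]
        # map order within chromosome: representative = lowest map position
        order = idx[np.argsort(markers.map.position_cm[idx], kind="stable")]
        assigned = np.zeros(len(order), dtype=bool)
        sub = centered[:, order]
        subsd = sd[order]
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(subsd > 0, sub / (subsd * np.sqrt(n)), 0.0)
        corr = norm.T @ norm
        for a in range(len(order)):
            if assigned[a]:
                continue
            members = [a]
            assigned[a] = True
            if subsd[a] > 0:
                for b in range(a + 1, len(order)):
                    if assigned[b] or subsd[b] <= 0:
                        continue
                    if abs(corr[a, b] ** 2 - 1.0) <= tol:
                        members.append(b)
                        assigned[b] = True
            rep = markers.map.marker_id[order[a]]
            clusters[rep] = [markers.map.marker_id[order[x]] for x in members]
            for b in members[1:]:
                keep[order[b]] = False
    return markers.subset_markers(np.where(keep)[0]), clusters


def impute_marker_means(markers: MarkerMatrix) -> MarkerMatrix:
    """Replace missing entries by the marker mean code (for kernel and
    design-matrix construction only; scans delete case-wise instead)."""
    codes = markers.codes.copy()
    mu = np.nanmean(codes, axis=0)
    nanmask = np.isnan(codes)
    codes[nanmask] = np.broadcast_to(mu, codes.shape)[nanmask]
    out = MarkerMatrix.__new__(MarkerMatrix)
    out.codes = codes
    out.map = markers.map
    out.individual_ids = markers.individual_ids
    out.group = markers.group
    return out


def f_infinity_design(markers: MarkerMatrix, impute: bool = False) -> DesignMatrices:
    """A = genotype code, D = heterozygote indicator.

    With ``impute``, missing codes are first replaced by marker means (the
    dominance indicator for an imputed entry is the marker heterozygosity
    rate contribution 0 — imputed entries are never counted heterozygous).
    """
    codes = markers.codes
    if np.isnan(codes).any():
        if not impute:
            raise DataError("missing genotypes present; set impute=True or pre-impute")
        D = (codes == 0).astype(float)
        codes = impute_marker_means(markers).codes
    else:
        D = (codes == 0).astype(float)
    return DesignMatrices(codes.copy(), D, markers.map, markers.individual_ids)


def code_from_design(design: DesignMatrices) -> np.ndarray:
    """Inverse of f_infinity_design on exact codes: code = A (D flags code 0)."""
    return design.A.copy()


# ---------------------------------------------------------------------------
# Minimal VCF reader (GT field only) for real-data entry
# ---------------------------------------------------------------------------


def read_vcf_genotypes(path, group: Sequence | None = None) -> MarkerMatrix:
    """Read a plain-text VCF keeping only biallelic sites and the GT field.

    0/0 -> -1, 0/1 or 1/0 (phased or not) -> 0, 1/1 -> +1, ./. -> missing.
    Positions are taken as bp and exposed on the cM column as bp/1e6.
    """
    from .core import GeneticMap

    chroms, mids, pos, rows = [], [], [], []
    samples = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if samples is None:
                raise DataError("VCF header line missing")
            chrom, p, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt:
                continue  # multi-allelic
            fmt = parts[8].split(":")
            try:
                gt_i = fmt.index("GT")
            except ValueError:
                continue
            row = []
            for s in parts[9:]:
                gt = s.split(":")[gt_i].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    row.append(np.nan)
                else:
                    dose = sum(int(a) for a in alleles)
                    row.append({0: -1.0, 1: 0.0, 2: 1.0}[dose])
            chroms.append(chrom)
            mids.append(vid if vid != "." else f"{chrom}:{p}")
            pos.append(float(p) / 1e6)
            rows.append(row)
    gmap = GeneticMap(
        np.array(chroms, dtype=object), np.array(mids, dtype=object), np.array(pos)
    )
    codes = np.array(rows).T
    if group is None:
        group = [
            GROUP_HYBRID if np.any(codes[i] == 0) else GROUP_INBRED
            for i in range(codes.shape[0])
        ]
    return MarkerMatrix(codes, gmap, np.array(samples, dtype=object), np.array(group, dtype=object))
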