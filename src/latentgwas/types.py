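"""Core in-memory containers shared across the pipeline.

The containers are thin, validated wrappers around NumPy arrays and pandas
DataFrames: a genotype dosage panel with its variant map, a per-sample
covariate table, a stack of co-registered 3D volumes with one shared ROI
label map, per-trait GWAS summary statistics, and tables of clumped loci.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing dosage (valid dosages live in [0, 2]).
MISSING = -1.0

#: Canonical summary-statistics column order used by every writer/reader.
SUMSTAT_COLUMNS = ["CHR", "POS", "ID", "A1", "A2", "BETA", "SE", "Z", "P", "N", "MAF"]


class ValidationError(ValueError):
    """An input container violates one of its documented invariants."""


@dataclass
class GenotypePanel:
    """samples x variants alt-allele dosage matrix plus a variant map.

    ``variants`` has columns ``id, chrom, pos, ref, alt`` with 1-based
    positions strictly increasing within each chromosome. Dosages are
    alt-allele counts in [0, 2]; missing entries hold :data:`MISSING`.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.validate()

    def validate(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValidationError(
                f"dosage rows ({n}) != number of samples ({len(self.sample_ids)})"
            )
        if m != len(self.variants):
            raise ValidationError(
                f"dosage columns ({m}) != number of variants ({len(self.variants)})"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids are not unique")
        required = {"id", "chrom", "pos", "ref", "alt"}
        if not required.issubset(self.variants.columns):
            raise ValidationError(f"variant map lacks columns {required - set(self.variants.columns)}")
        if self.variants["id"].duplicated().any():
            dup = self.variants.loc[self.variants["id"].duplicated(), "id"].iloc[0]
            raise ValidationError(f"duplicated variant id {dup!r}")
        if (self.variants["ref"] == self.variants["alt"]).any():
            raise ValidationError("ref allele equals alt allele for some variant")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValidationError(f"positions not strictly increasing on chrom {chrom}")
        observed = self.dosages[self.dosages != MISSING]
        if observed.size and ((observed < 0) | (observed > 2)).any():
            raise ValidationError("non-missing dosages must lie in [0, 2]")

    # -- derived quantities ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def alt_freq(self) -> np.ndarray:
        """Per-variant alt-allele frequency over non-missing calls."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        with np.errstate(invalid="ignore"):
            return np.asarray(d.mean(axis=0).filled(np.nan)) / 2.0

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def variant_missingness(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def dosages_imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-variant mean."""
        d = self.dosages.copy()
        miss = d == MISSING
        if miss.any():
            col_mean = np.where(
                miss.all(axis=0), 1.0, np.ma.masked_array(d, miss).mean(axis=0).filled(1.0)
            )
            d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
        return d

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypePanel":
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        variant_idx = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in sample_idx],
            variants=self.variants.iloc[variant_idx].reset_index(drop=True),
            dosages=self.dosages[np.ix_(sample_idx, variant_idx)],
        )


@dataclass
class CovariateTable:
    """Per-sample confounders: age (years), sex (0/1), batch, genetic PCs.

    ``table`` is indexed by sample id with columns ``age``, ``sex``,
    ``batch`` and zero or more ``pc1..pck`` columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("age", "sex"):
            if col not in t.columns:
                raise ValidationError(f"covariate table lacks column {col!r}")
            if t[col].isna().any():
                raise ValidationError(f"missing values in covariate {col!r}")
        if t.index.duplicated().any():
            raise ValidationError("duplicated sample ids in covariate table")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    def pc_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("pc")]

    def design_matrix(self, include: Sequence[str] | None = None) -> np.ndarray:
        """Intercept + age + sex + batch dummies (drop-first) + genetic PCs."""
        t = self.table
        cols = [np.ones(len(t))]
        wanted = set(include) if include is not None else None

        def use(name: str) -> bool:
            return wanted is None or name in wanted

        if use("age"):
            cols.append(t["age"].to_numpy(float))
        if use("sex"):
            cols.append(t["sex"].to_numpy(float))
        if "batch" in t.columns and use("batch"):
            dummies = pd.get_dummies(t["batch"], drop_first=True, dtype=float)
            cols.extend(dummies[c].to_numpy() for c in dummies.columns)
        for c in self.pc_columns():
            if use(c) or (wanted is not None and "pcs" in wanted):
                cols.append(t[c].to_numpy(float))
        return np.column_stack(cols)

    def align(self, sample_ids: Sequence[str]) -> "CovariateTable":
        return CovariateTable(self.table.loc[list(sample_ids)])


@dataclass
class EffectSpec:
    """Ground-truth generative effects planted into a synthetic cohort.

    ``entries`` are ``(variant_index, roi_label, beta, target)`` tuples where
    ``target`` is ``"radius"`` (voxels per alt allele) or ``"intensity"``
    (intensity units per alt allele).
    """

    entries: list[tuple[int, int, float, str]] = field(default_factory=list)
    age_slope: float = 0.0
    sex_offset: float = 0.0
    #: global scan-brightness shift per decade of age — emulates the
    #: age-predictable intensity component that conditioning can discard
    age_intensity_slope: float = 0.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")
        norm = []
        for e in self.entries:
            if len(e) == 3:
                e = (*e, "radius")
            vi, roi, beta, target = e
            if target not in ("radius", "intensity"):
                raise ValidationError(f"unknown effect target {target!r}")
            norm.append((int(vi), int(roi), float(beta), target))
        self.entries = norm

    def validate_against(self, n_variants: int, roi_labels: Sequence[int]) -> None:
        labels = set(int(r) for r in roi_labels)
        for vi, roi, _, _ in self.entries:
            if not 0 <= vi < n_variants:
                raise ValidationError(f"effect variant index {vi} out of range")
            if roi not in labels:
                raise ValidationError(f"effect references unknown ROI label {roi}")


@dataclass
class VolumeStack:
    """Co-registered 3D intensity volumes sharing one integer ROI label map."""

    volumes: np.ndarray          # (n_samples, nx, ny, nz)
    roi_labels: np.ndarray       # (nx, ny, nz) int, 0 = background
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes)
        self.roi_labels = np.asarray(self.roi_labels, dtype=int)
        if self.volumes.ndim != 4:
            raise ValidationError("volumes must be a 4D (n, x, y, z) array")
        if self.volumes.shape[1:] != self.roi_labels.shape:
            raise ValidationError("ROI label map shape differs from volume shape")
        if self.sample_ids is not None and len(self.sample_ids) != len(self.volumes):
            raise ValidationError("sample_ids length differs from number of volumes")

    @property
    def n_samples(self) -> int:
        return self.volumes.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[1:]

    def roi_label_values(self) -> np.ndarray:
        labels = np.unique(self.roi_labels)
        return labels[labels != 0]


@dataclass
class SummaryStats:
    """Per-variant association results for one trait.

    ``table`` follows :data:`SUMSTAT_COLUMNS`; ``A1`` is the effect (alt)
    allele and ``BETA`` is per alt allele in trait-SD units.
    """

    table: pd.DataFrame
    trait: str = "trait"

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"summary statistics lack columns {missing}")
        self.table = self.table.reset_index(drop=True)
        if self.table["ID"].duplicated().any():
            raise ValidationError("duplicated variant id in summary statistics")
        p = self.table["P"].to_numpy(float)
        if ((p <= 0) | (p > 1)).any():
            raise ValidationError("p-values must lie in (0, 1]")
        if (self.table["SE"].to_numpy(float) <= 0).any():
            raise ValidationError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class LocusTable:
    """Clumped independent loci: one row per locus plus member lists."""

    table: pd.DataFrame  # columns: index_id, chrom, pos, start, end, min_p, n_members, trait
    members: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.table) != len(self.members):
            raise ValidationError("one member list required per locus")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @staticmethod
    def empty(trait: str = "trait") -> "LocusTable":
        cols = ["index_id", "chrom", "pos", "start", "end", "min_p", "n_members", "trait"]
        return LocusTable(pd.DataFrame(columns=cols), [])


@dataclass
class QCReport:
    """Counts removed at each genotype-QC stage, in application order."""

    steps: list[tuple[str, int]]
    survivors: int
    input_count: int
    samples_removed: int = 0

    def __post_init__(self) -> None:
        removed = sum(n for _, n in self.steps)
        if removed + self.survivors != self.input_count:
            raise ValidationError("QC counts do not add up to the input count")

    def as_dict(self) -> dict:
        return {
            "input_variants": self.input_count,
            "removed": dict(self.steps),
            "surviving_variants": self.survivors,
            "samples_removed": self.samples_removed,
        }


@dataclass
class LatentMatrix:
    """Per-sample feature vectors from one extractor (``cvae`` | ``slice2d``)."""

    sample_ids: list[str]
    features: np.ndarray
    extractor: str = "cvae"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] != len(self.sample_ids):
            raise ValidationError("features must be (n_samples, d)")
        if not np.isfinite(self.features).all():
            raise ValidationError("latent features must be finite")


def summary_stats_from_arrays(
    variants: pd.DataFrame,
    beta: np.ndarray,
    se: np.ndarray,
    p: np.ndarray,
    n: np.ndarray | int,
    maf: np.ndarray | float,
    trait: str,
) -> SummaryStats:
    """Assemble a :class:`SummaryStats` from a variant map and result arrays."""
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    with np.errstate(invalid="ignore"):
        z = np.where(np.isinf(se), 0.0, beta / se)
    table = pd.DataFrame(
        {
            "CHR": variants["chrom"].to_numpy(),
            "POS": variants["pos"].to_numpy(),
            "ID": variants["id"].to_numpy(),
            "A1": variants["alt"].to_numpy(),
            "A2": variants["ref"].to_numpy(),
            "BETA": beta,
            "SE": se,
            "Z": z,
            "P": np.asarray(p, float),
            "N": np.broadcast_to(np.asarray(n), beta.shape).astype(int),
            "MAF": np.broadcast_to(np.asarray(maf, float), beta.shape),
        }
    )
    return SummaryStats(table, trait=trait)
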