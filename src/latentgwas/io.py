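"""File formats: dosage TSV with a variant sidecar, a minimal VCF dialect,
NIfTI volume stacks (with a compressed-array fallback bundle), summary
statistics, loci, PGS weights and latent/score tables.

All parsers attach file and line context to their errors.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    SUMSTAT_COLUMNS,
    CovariateTable,
    GenotypePanel,
    LatentMatrix,
    LocusTable,
    SummaryStats,
    VolumeStack,
)
from .pgs import PGSWeights

__all__ = [
    "ParseError",
    "write_genotypes", "read_genotypes",
    "write_vcf", "read_vcf",
    "write_volumes", "read_volumes",
    "write_sumstats", "read_sumstats",
    "write_loci", "write_weights", "read_weights",
    "write_latents", "read_latents",
    "write_covariates", "read_covariates",
]

_FLOAT_FMT = "%.10g"


class ParseError(ValueError):
    """Malformed input file; message carries file and line number."""

    def __init__(self, path, line: int | None, message: str):
        loc = f"{path}" if line is None else f"{path}:{line}"
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line = line


# ---------------------------------------------------------------------------
# dosage TSV + sidecar
# ---------------------------------------------------------------------------

def write_genotypes(panel: GenotypePanel, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.dosage.tsv`` and ``<prefix>.variants.tsv``.

    The dosage table has a ``sample_id`` key column then one column per
    variant id; missing dosages are written as ``NA``. Round-trips
    bit-exactly through :func:`read_genotypes`.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    dosage_path = Path(str(prefix) + ".dosage.tsv")
    sidecar_path = Path(str(prefix) + ".variants.tsv")
    ids = panel.variants["id"].tolist()
    with open(dosage_path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(ids) + "\n")
        for i, sid in enumerate(panel.sample_ids):
            row = panel.dosages[i]
            vals = ["NA" if v == MISSING else repr(float(v)) for v in row]
            fh.write(sid + "\t" + "\t".join(vals) + "\n")
    panel.variants[["id", "chrom", "pos", "ref", "alt"]].to_csv(sidecar_path, sep="\t", index=False)
    return dosage_path, sidecar_path


def read_genotypes(prefix: str | Path) -> GenotypePanel:
    """Read the dosage TSV dialect written by :func:`write_genotypes`."""
    prefix = Path(prefix)
    dosage_path = Path(str(prefix) + ".dosage.tsv")
    sidecar_path = Path(str(prefix) + ".variants.tsv")
    with open(dosage_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "sample_id":
            raise ParseError(dosage_path, 1, "header must start with 'sample_id'")
        var_ids = header[1:]
        if len(set(var_ids)) != len(var_ids):
            dup = next(v for v in var_ids if var_ids.count(v) > 1)
            raise ParseError(dosage_path, 1, f"duplicated variant id {dup!r} in header")
        sample_ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    dosage_path, lineno,
                    f"expected {len(header)} fields, found {len(parts)}",
                )
            sample_ids.append(parts[0])
            try:
                rows.append([MISSING if v == "NA" else float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(dosage_path, lineno, f"bad dosage value ({exc})") from None
    variants = pd.read_csv(sidecar_path, sep="\t", dtype={"chrom": str})
    if list(variants["id"]) != var_ids:
        raise ParseError(sidecar_path, None, "variant ids disagree with the dosage header")
    for g, grp in variants.groupby("chrom", sort=False):
        if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
            bad = int(np.flatnonzero(np.diff(grp["pos"].to_numpy()) <= 0)[0])
            raise ParseError(
                sidecar_path, int(grp.index[bad + 1]) + 2,
                f"positions not strictly increasing on chrom {g}",
            )
    return GenotypePanel(sample_ids, variants, np.array(rows, dtype=float))


# ---------------------------------------------------------------------------
# minimal VCF
# ---------------------------------------------------------------------------

def write_vcf(panel: GenotypePanel, path: str | Path) -> Path:
    """Minimal VCFv4.2 with GT genotypes from rounded dosages."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.variants["chrom"].astype(str).unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        for j, v in panel.variants.iterrows():
            calls = []
            for i in range(panel.n_samples):
                d = panel.dosages[i, j]
                calls.append("./." if d == MISSING else gt_map[int(np.clip(round(d), 0, 2))])
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )
    return path


def read_vcf(path: str | Path) -> GenotypePanel:
    """Minimal VCF reader: GT to dosage; half-calls and ``./.`` to missing."""
    path = Path(path)
    sample_ids: list[str] | None = None
    var_rows, dosage_cols, seen_ids = [], [], set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ParseError(path, lineno, "VCF header has no sample columns")
                sample_ids = fields[9:]
                continue
            if sample_ids is None:
                raise ParseError(path, lineno, "data line before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(sample_ids):
                raise ParseError(
                    path, lineno,
                    f"expected {9 + len(sample_ids)} fields, found {len(fields)}",
                )
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if vid in seen_ids:
                raise ParseError(path, lineno, f"duplicated variant id {vid!r}")
            seen_ids.add(vid)
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise ParseError(path, lineno, "FORMAT lacks GT")
            gt_idx = fmt.index("GT")
            try:
                pos_i = int(pos)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer POS {pos!r}") from None
            doses = []
            for call in fields[9:]:
                gt = call.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles or gt in (".", "./."):
                    doses.append(MISSING)
                else:
                    try:
                        doses.append(float(sum(int(a) for a in alleles)))
                    except ValueError:
                        raise ParseError(path, lineno, f"bad GT {gt!r}") from None
            var_rows.append({"id": vid, "chrom": chrom, "pos": pos_i, "ref": ref, "alt": alt})
            dosage_cols.append(doses)
    if sample_ids is None:
        raise ParseError(path, None, "no #CHROM header found")
    variants = pd.DataFrame(var_rows)
    for g, grp in variants.groupby("chrom", sort=False):
        if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
            raise ParseError(path, None, f"positions not strictly increasing on chrom {g}")
    return GenotypePanel(sample_ids, variants, np.array(dosage_cols, dtype=float).T)


# ---------------------------------------------------------------------------
# volumes: NIfTI (4D stack + 3D label map) with .npz fallback
# ---------------------------------------------------------------------------

def write_volumes(stack: VolumeStack, prefix: str | Path, format: str = "nifti") -> list[Path]:
    """Write the stack as NIfTI (``<prefix>.nii`` + ``<prefix>.labels.nii``)
    or as a compressed-array bundle (``<prefix>.npz``)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ids = stack.sample_ids or [f"S{i + 1:05d}" for i in range(stack.n_samples)]
    if format == "npz":
        path = Path(str(prefix) + ".npz")
        np.savez_compressed(
            path,
            volumes=stack.volumes,
            roi_labels=stack.roi_labels,
            voxel_size=np.asarray(stack.voxel_size, float),
            sample_ids=np.asarray(ids, dtype="U"),
        )
        return [path]
    if format != "nifti":
        raise ValueError("format must be 'nifti' or 'npz'")
    import nibabel as nib

    affine = np.diag([*stack.voxel_size, 1.0])
    vol_path = Path(str(prefix) + ".nii")
    lab_path = Path(str(prefix) + ".labels.nii")
    img = nib.Nifti1Image(np.moveaxis(stack.volumes, 0, -1).astype(np.float32), affine)
    nib.save(img, vol_path)
    nib.save(nib.Nifti1Image(stack.roi_labels.astype(np.int16), affine), lab_path)
    ids_path = Path(str(prefix) + ".samples.tsv")
    pd.Series(ids, name="sample_id").to_csv(ids_path, sep="\t", index=False)
    return [vol_path, lab_path, ids_path]


def read_volumes(prefix: str | Path, declared_labels=None) -> VolumeStack:
    """Read a stack written by :func:`write_volumes` (either format)."""
    prefix = Path(prefix)
    npz = Path(str(prefix) + ".npz")
    if npz.exists():
        with np.load(npz) as d:
            stack = VolumeStack(
                d["volumes"], d["roi_labels"],
                voxel_size=tuple(d["voxel_size"]),
                sample_ids=list(d["sample_ids"]),
            )
    else:
        import nibabel as nib

        vol_path = Path(str(prefix) + ".nii")
        lab_path = Path(str(prefix) + ".labels.nii")
        if not vol_path.exists():
            raise ParseError(vol_path, None, "volume file not found")
        img = nib.load(vol_path)
        labels = nib.load(lab_path).get_fdata().astype(int)
        vols = np.moveaxis(np.asarray(img.dataobj), -1, 0)
        if vols.shape[1:] != labels.shape:
            raise ParseError(lab_path, None, "label map shape differs from volume shape")
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
        ids_path = Path(str(prefix) + ".samples.tsv")
        ids = pd.read_csv(ids_path, sep="\t")["sample_id"].astype(str).tolist() if ids_path.exists() else None
        stack = VolumeStack(vols, labels, voxel_size=voxel_size, sample_ids=ids)
    if declared_labels is not None:
        found = set(int(v) for v in np.unique(stack.roi_labels)) - {0}
        extra = found - set(int(v) for v in declared_labels)
        if extra:
            raise ParseError(prefix, None, f"undeclared ROI labels {sorted(extra)}")
    return stack


# ---------------------------------------------------------------------------
# tabular artifacts
# ---------------------------------------------------------------------------

def write_sumstats(stats: SummaryStats, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = SUMSTAT_COLUMNS + [c for c in stats.table.columns if c not in SUMSTAT_COLUMNS]
    stats.table[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_sumstats(path: str | Path, trait: str | None = None) -> SummaryStats:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in SUMSTAT_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(path, 1, f"summary statistics lack columns {missing}")
    return SummaryStats(table, trait=trait or path.stem)


def write_loci(loci: LocusTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = loci.table.copy()
    t["members"] = [",".join(m) for m in loci.members]
    t.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def write_weights(weights: PGSWeights, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    weights.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_weights(path: str | Path) -> PGSWeights:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing = {"ID", "EA", "OA", "WEIGHT"} - set(table.columns)
    if missing:
        raise ParseError(path, 1, f"weights lack columns {sorted(missing)}")
    return PGSWeights(table)


def write_latents(latents: LatentMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        latents.features,
        columns=[f"f{j + 1}" for j in range(latents.features.shape[1])],
    )
    df.insert(0, "sample_id", latents.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def read_latents(path: str | Path, extractor: str = "cvae") -> LatentMatrix:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ParseError(path, 1, "latent table lacks sample_id column")
    return LatentMatrix(
        sample_ids=df["sample_id"].astype(str).tolist(),
        features=df.drop(columns="sample_id").to_numpy(float),
        extractor=extractor,
    )


def write_covariates(cov: CovariateTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cov.table.to_csv(path, sep="\t", float_format="%.12g")
    return path


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CovariateTable(df)
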