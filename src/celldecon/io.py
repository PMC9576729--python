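"""Readers and writers for expression matrices, annotations, bundles, results.

Gene identifiers are matched on upper-cased symbol strings at every read
site; duplicate rows surviving case-normalization are collapsed by
summation with a logged warning. A profile bundle serializes to a
directory holding one JSON metadata file plus one genes x cell-types TSV
per profile set (decimal text, 6 significant digits) so that bundles are
inspectable and diff-able.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .types import (
    CellTypeProfile,
    DeconvolutionResult,
    ProfileBundle,
    ProfileSet,
    normalize_gene_id,
)

__all__ = [
    "read_expression_matrix",
    "read_cell_annotations",
    "write_profile_bundle",
    "read_profile_bundle",
    "write_results",
    "write_reference_dataset",
    "load_reference_dataset",
    "load_reference_collection",
]

logger = logging.getLogger(__name__)


def _collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    df.index = [normalize_gene_id(g) for g in df.index]
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("collapsing %d duplicated gene ids by summation: %s",
                       len(dups), dups[:10])
        df = df.groupby(level=0, sort=False).sum()
    return df


def read_expression_matrix(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a genes x columns expression matrix (TSV, CSV, or 10x MTX triplet).

    For ``mtx_10x``, ``path`` is a directory containing ``matrix.mtx``,
    ``features.tsv`` (or ``genes.tsv``) and ``barcodes.tsv``. Duplicate
    gene ids are collapsed by summation; negative values are rejected.
    """
    path = Path(path)
    if format is None:
        format = "mtx_10x" if path.is_dir() else ("csv" if path.suffix == ".csv" else "tsv")
    if format in ("tsv", "csv"):
        if not path.exists():
            raise FileNotFoundError(path)
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - message pass-through
            raise ValueError(f"malformed {format} file {path}: {exc}") from exc
        if df.empty or df.shape[1] == 0:
            raise ValueError(f"malformed {format} file {path}: no data columns")
        non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
        if len(non_numeric):
            raise ValueError(
                f"malformed {format} file {path}: non-numeric column(s) {list(non_numeric)}"
            )
    elif format == "mtx_10x":
        mtx = path / "matrix.mtx"
        feats = path / "features.tsv"
        if not feats.exists():
            feats = path / "genes.tsv"
        barcodes = path / "barcodes.tsv"
        missing = [p.name for p in (mtx, feats, barcodes) if not p.exists()]
        if missing:
            raise FileNotFoundError(f"incomplete MTX triplet in {path}: missing {missing}")
        m = mmread(mtx).toarray()
        genes = pd.read_csv(feats, sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(barcodes, sep="\t", header=None)[0].tolist()
        if m.shape != (len(genes), len(cells)):
            raise ValueError(
                f"MTX shape {m.shape} does not match {len(genes)} features x {len(cells)} barcodes"
            )
        df = pd.DataFrame(m, index=genes, columns=cells)
    else:
        raise ValueError(f"unknown format {format!r}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative expression values in {path}")
    return _collapse_duplicates(df.astype(float))


def read_cell_annotations(
    path: str | Path,
    matrix_columns: list[str] | None = None,
    vocabulary: list[str] | None = None,
    exclude_diseased: bool = True,
) -> pd.DataFrame:
    """Read a per-cell annotation table (columns: cell_id, cell_type[, diseased]).

    Returns the table with a boolean ``usable`` column: cells flagged
    diseased are marked unusable when ``exclude_diseased`` (the default,
    mirroring the practice of dropping diseased cells from references).
    Cell ids absent from the expression matrix, or labels outside a
    supplied controlled vocabulary, raise errors naming the offenders.
    """
    path = Path(path)
    ann = pd.read_csv(path, sep="\t" if path.suffix != ".csv" else ",")
    required = {"cell_id", "cell_type"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation table {path} must have columns {sorted(required)}")
    ann["cell_id"] = ann["cell_id"].astype(str)
    if matrix_columns is not None:
        missing = sorted(set(ann["cell_id"]) - set(map(str, matrix_columns)))
        if missing:
            raise ValueError(
                f"annotation cell ids absent from expression matrix: {missing[:20]}"
            )
    if vocabulary is not None:
        unknown = sorted(set(ann["cell_type"]) - set(vocabulary))
        if unknown:
            raise ValueError(f"cell-type labels outside bundle vocabulary: {unknown}")
    if "diseased" in ann.columns:
        diseased = ann["diseased"].astype(bool)
    else:
        diseased = pd.Series(False, index=ann.index)
    ann["usable"] = ~(diseased & exclude_diseased)
    if exclude_diseased and diseased.any():
        logger.info("excluding %d diseased cells", int(diseased.sum()))
    return ann


def _fmt6(x: float) -> str:
    return f"{x:.6g}"


def _gene_list_digest(genes: list[str]) -> str:
    return hashlib.sha256("\n".join(genes).encode()).hexdigest()


def write_profile_bundle(bundle: ProfileBundle, directory: str | Path) -> Path:
    """Serialize a bundle to a directory (JSON metadata + per-set TSVs)."""
    if not bundle.profile_sets:
        raise ValueError("refusing to write a bundle with no profile sets")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "group_name": bundle.group_name,
        "cell_types": bundle.cell_types,
        "n_genes": len(bundle.gene_universe),
        "gene_digest": _gene_list_digest(bundle.gene_universe),
        "config_snapshot": bundle.config_snapshot,
        "profile_genes": bundle.profile_genes(),
        "sets": [
            {
                "set_id": s.set_id,
                "rank": s.rank,
                "training_score": s.training_score,
                "file": f"set_{i:04d}.tsv",
                "sources": {ct: list(p.source) for ct, p in s.profiles.items()},
            }
            for i, s in enumerate(bundle.profile_sets)
        ],
    }
    (directory / "genes.tsv").write_text("\n".join(bundle.gene_universe) + "\n")
    for i, s in enumerate(bundle.profile_sets):
        mat = s.matrix().reindex(bundle.gene_universe)
        lines = ["gene\t" + "\t".join(mat.columns)]
        for g, row in zip(mat.index, mat.to_numpy()):
            lines.append(g + "\t" + "\t".join(_fmt6(v) for v in row))
        (directory / f"set_{i:04d}.tsv").write_text("\n".join(lines) + "\n")
    (directory / "bundle.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_profile_bundle(directory: str | Path) -> ProfileBundle:
    """Read a serialized bundle back; integrity failures raise errors."""
    directory = Path(directory)
    meta_path = directory / "bundle.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing bundle metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    genes_path = directory / "genes.tsv"
    if not genes_path.exists():
        raise FileNotFoundError(f"missing bundle component {genes_path}")
    genes = genes_path.read_text().splitlines()
    if len(genes) != meta["n_genes"] or _gene_list_digest(genes) != meta["gene_digest"]:
        raise ValueError(f"bundle integrity error: gene list in {genes_path} was modified")

    sets = []
    for entry in meta["sets"]:
        f = directory / entry["file"]
        if not f.exists():
            raise FileNotFoundError(f"missing bundle component {f}")
        mat = pd.read_csv(f, sep="\t", index_col=0)
        if list(mat.index) != genes:
            raise ValueError(f"bundle integrity error: gene order mismatch in {f}")
        profiles = {
            ct: CellTypeProfile(
                cell_type=ct,
                values=mat[ct],
                profile_genes=list(meta["profile_genes"][ct]),
                source=tuple(entry["sources"][ct]),
            )
            for ct in mat.columns
        }
        s = ProfileSet(
            set_id=entry["set_id"],
            profiles=profiles,
            training_score=entry["training_score"],
        )
        sets.append(s)
    bundle = ProfileBundle(
        group_name=meta["group_name"],
        cell_types=meta["cell_types"],
        gene_universe=genes,
        profile_sets=sets,
        config_snapshot=meta["config_snapshot"],
    )
    return bundle


def write_reference_dataset(dataset, directory: str | Path) -> Path:
    """Write one reference dataset as matrix.tsv + annotations.tsv + meta.json."""
    from .types import ReferenceDataset  # local import to avoid cycle noise

    assert isinstance(dataset, ReferenceDataset)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(dataset.counts, index=dataset.gene_ids, columns=dataset.cell_ids)
    df.to_csv(directory / "matrix.tsv", sep="\t")
    ann = pd.DataFrame({"cell_id": dataset.cell_ids, "cell_type": dataset.cell_types})
    if dataset.diseased_flags is not None:
        ann["diseased"] = dataset.diseased_flags
    ann.to_csv(directory / "annotations.tsv", sep="\t", index=False)
    meta = {"dataset_id": dataset.dataset_id, "platform": dataset.platform.value}
    if dataset.gene_lengths is not None:
        meta["gene_lengths"] = [float(x) for x in dataset.gene_lengths]
    (directory / "meta.json").write_text(json.dumps(meta))
    return directory


def load_reference_dataset(directory: str | Path):
    """Load a dataset directory written by :func:`write_reference_dataset`."""
    from .types import Platform, ReferenceDataset

    directory = Path(directory)
    mtx_dir = directory if (directory / "matrix.mtx").exists() else None
    if mtx_dir is not None:
        df = read_expression_matrix(directory, format="mtx_10x")
    else:
        df = read_expression_matrix(directory / "matrix.tsv", format="tsv")
    meta = {}
    if (directory / "meta.json").exists():
        meta = json.loads((directory / "meta.json").read_text())
    ann = read_cell_annotations(
        directory / "annotations.tsv", matrix_columns=list(df.columns)
    )
    ann = ann[ann["usable"]]
    df = df[ann["cell_id"].tolist()]
    lengths = meta.get("gene_lengths")
    return ReferenceDataset(
        dataset_id=meta.get("dataset_id", directory.name),
        counts=df.to_numpy(),
        gene_ids=list(df.index),
        cell_ids=list(df.columns),
        cell_types=ann["cell_type"].tolist(),
        platform=Platform(meta.get("platform", "three_prime_umi")),
        gene_lengths=np.asarray(lengths, dtype=float) if lengths is not None else None,
    )


def load_reference_collection(directory: str | Path) -> list:
    """Load every dataset subdirectory of a collection directory."""
    directory = Path(directory)
    subdirs = sorted(
        d for d in directory.iterdir()
        if d.is_dir() and ((d / "matrix.tsv").exists() or (d / "matrix.mtx").exists())
    )
    if not subdirs:
        raise FileNotFoundError(f"no dataset subdirectories under {directory}")
    return [load_reference_dataset(d) for d in subdirs]


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def write_results(results: list[DeconvolutionResult], directory: str | Path) -> Path:
    """Write proportions as TSV plus a JSON sidecar with fit diagnostics."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    types = sorted({ct for r in results for ct in r.proportions})
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id}
        row.update({ct: r.proportions.get(ct, 0.0) for ct in types})
        row["undetermined"] = r.undetermined
        rows.append(row)
    pd.DataFrame(rows).set_index("sample_id").to_csv(directory / "proportions.tsv", sep="\t")
    sidecar = {
        r.sample_id: {
            "pvalues": r.pvalues,
            "significance": {ct: _stars(p) for ct, p in r.pvalues.items()},
            "weights": r.weights,
            "fit_rmse": r.fit_rmse,
            "used_set_ids": r.used_set_ids,
            "undetermined": r.undetermined,
            "alpha": r.alpha,
        }
        for r in results
    }
    (directory / "details.json").write_text(json.dumps(sidecar, indent=1))
    return directory
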