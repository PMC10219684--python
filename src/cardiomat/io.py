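"""Validated readers and writers for the pipeline's table and image formats.

Tab-separated values (header row, UTF-8, '.' decimal) are the canonical
table dialect; counts are also accepted as MatrixMarket (.mtx) with
sidecar gene/sample label files. Validation failures name the offending
row/column so malformed inputs fail loudly before any compute.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_counts_tsv",
    "read_counts_mtx",
    "read_design_tsv",
    "read_regulon_tsv",
    "read_trace_csv",
    "read_image",
    "read_ct_tsv",
    "read_plate_tsv",
    "read_manifest_yaml",
    "read_validate",
    "write_table",
    "write_image",
    "write_results",
    "file_checksum",
]

SCHEMAS = (
    "counts_tsv",
    "counts_mtx",
    "design_tsv",
    "regulon_tsv",
    "trace_csv",
    "image",
    "ct_tsv",
    "plate_tsv",
    "manifest_yaml",
)


def _check_unique(index: pd.Index, what: str, path: Path) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValueError(f"{path}: duplicate {what} id {dup!r}")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Gene × sample integer count matrix; first column is the gene id."""
    path = Path(path)
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene"
    _check_unique(counts.index, "gene", path)
    _check_unique(counts.columns, "sample", path)
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in count matrix")
    neg = np.argwhere(arr < 0)
    if len(neg):
        g, s = neg[0]
        raise ValueError(
            f"{path}: negative count at gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
        )
    if not np.allclose(arr, np.round(arr)):
        bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ValueError(
            f"{path}: non-integer count at gene {counts.index[bad[0]]!r}, "
            f"sample {counts.columns[bad[1]]!r}"
        )
    return counts.astype(np.int64)


def read_counts_mtx(path: str | Path) -> pd.DataFrame:
    """Counts in MatrixMarket form: ``X.mtx`` + ``X.genes.txt`` + ``X.samples.txt``."""
    from scipy.io import mmread

    path = Path(path)
    stem = path.with_suffix("")
    genes = stem.with_suffix(".genes.txt").read_text().split()
    samples = stem.with_suffix(".samples.txt").read_text().split()
    mat = mmread(path)
    if hasattr(mat, "toarray"):
        mat = mat.toarray()
    mat = np.asarray(mat)
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative count in matrix")
    return counts.astype(np.int64)


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    design = pd.read_csv(path, sep="\t", index_col=0)
    design.index.name = "sample"
    _check_unique(design.index, "sample", path)
    for col in ("condition", "dataset"):
        if col not in design.columns:
            raise ValueError(f"{path}: design table missing column {col!r}")
    if "replicate" not in design.columns:
        design["replicate"] = design.groupby("condition").cumcount() + 1
    return design


def read_regulon_tsv(path: str | Path) -> pd.DataFrame:
    """Regulon edges: columns ``tf, confidence, target, mor`` with mor ∈ {1, −1}."""
    path = Path(path)
    edges = pd.read_csv(path, sep="\t")
    required = ["tf", "confidence", "target", "mor"]
    missing = [c for c in required if c not in edges.columns]
    if missing:
        raise ValueError(f"{path}: regulon table missing columns {missing}")
    bad = ~edges["mor"].isin([1, -1])
    if bad.any():
        row = int(edges.index[bad][0])
        raise ValueError(f"{path}: row {row}: mor must be 1 or -1, got {edges.loc[row, 'mor']!r}")
    from .activity import GRADE_ORDER

    bad = ~edges["confidence"].isin(GRADE_ORDER)
    if bad.any():
        row = int(edges.index[bad][0])
        raise ValueError(f"{path}: row {row}: invalid confidence {edges.loc[row, 'confidence']!r}")
    dup = edges.duplicated(subset=["tf", "target"])
    if dup.any():
        row = int(edges.index[dup][0])
        raise ValueError(f"{path}: row {row}: duplicate edge ({edges.loc[row, 'tf']}, {edges.loc[row, 'target']})")
    return edges[required].copy()


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    """Long-format traces: ``condition, video_id, cell_id, time_s, intensity``."""
    path = Path(path)
    traces = pd.read_csv(path)
    required = ["video_id", "cell_id", "time_s", "intensity"]
    missing = [c for c in required if c not in traces.columns]
    if missing:
        raise ValueError(f"{path}: trace table missing columns {missing}")
    if "condition" not in traces.columns:
        traces["condition"] = "all"
    if not np.isfinite(traces["intensity"].to_numpy(dtype=float)).all():
        row = int(traces.index[~np.isfinite(traces["intensity"].astype(float))][0])
        raise ValueError(f"{path}: row {row}: non-finite intensity")
    return traces


def read_image(path: str | Path) -> np.ndarray:
    """Grayscale TIFF/PNG as a float 2-D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {img.shape}")
    return img


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    """Ct table: gene × sample matrix of cycle-threshold values."""
    path = Path(path)
    ct = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    ct.index.name = "gene"
    _check_unique(ct.index, "gene", path)
    if not np.isfinite(ct.to_numpy()).all():
        g, s = np.argwhere(~np.isfinite(ct.to_numpy()))[0]
        raise ValueError(f"{path}: non-finite Ct at gene {ct.index[g]!r}, sample {ct.columns[s]!r}")
    return ct


def read_plate_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    plate = pd.read_csv(path, sep="\t")
    required = ["group", "luminescence", "absorbance_595"]
    missing = [c for c in required if c not in plate.columns]
    if missing:
        raise ValueError(f"{path}: plate table missing columns {missing}")
    if (plate["absorbance_595"].astype(float) <= 0).any():
        row = int(plate.index[plate["absorbance_595"].astype(float) <= 0][0])
        raise ValueError(f"{path}: row {row}: absorbance must be positive")
    return plate


def read_manifest_yaml(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise ValueError(f"{path}: manifest must be a YAML mapping")
    return manifest


_READERS = {
    "counts_tsv": read_counts_tsv,
    "counts_mtx": read_counts_mtx,
    "design_tsv": read_design_tsv,
    "regulon_tsv": read_regulon_tsv,
    "trace_csv": read_trace_csv,
    "image": read_image,
    "ct_tsv": read_ct_tsv,
    "plate_tsv": read_plate_tsv,
    "manifest_yaml": read_manifest_yaml,
}


def read_validate(path: str | Path, schema: str):
    """Read and validate ``path`` according to a named schema."""
    if schema not in _READERS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    return _READERS[schema](path)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    """Write a table; TSV by default, comma-separated for ``.csv`` paths."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=index)
    return path


def write_image(image: np.ndarray, path: str | Path) -> Path:
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_results(
    objects: dict[str, object],
    directory: str | Path,
    seed: int | None = None,
    parameters: dict | None = None,
    input_checksums: dict[str, str] | None = None,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Persist result objects and a run log.

    ``objects`` maps file names to DataFrames (written as TSV), arrays
    (TIFF for 2-D float images), strings or JSON-serializable mappings.
    Refuses to overwrite existing files unless ``overwrite`` is set. The
    run log records the package version, seed, full parameter set and
    input checksums.
    """
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, obj in objects.items():
        path = directory / name
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
        if isinstance(obj, pd.DataFrame):
            write_table(obj, path)
        elif isinstance(obj, pd.Series):
            write_table(obj.to_frame(), path)
        elif isinstance(obj, np.ndarray):
            write_image(obj, path)
        elif isinstance(obj, str):
            path.write_text(obj)
        else:
            path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
        written[name] = path

    log = {
        "version": __version__,
        "seed": seed,
        "parameters": parameters or {},
        "input_checksums": input_checksums or {},
        "outputs": sorted(written),
    }
    log_path = directory / "run_log.json"
    if log_path.exists() and not overwrite:
        raise FileExistsError(f"{log_path} exists; pass overwrite=True to replace it")
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True, default=str) + "\n")
    written["run_log.json"] = log_path
    return written
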