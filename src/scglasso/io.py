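"""Delimited-text readers/writers and report serialization.

All matrices travel as tab-delimited UTF-8 text with a header row and a
first column of region labels ('.' decimal, fixed dialect).  Cohort
manifests are tab-delimited tables (id, group, envelope path, fiber-
density path); reports are JSON with a provenance block (package
version, seed, configuration hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import ConnectivityMatrix
from .simulate import SubjectRecord

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_envelopes",
    "write_envelopes",
    "read_cohort_manifest",
    "write_cohort",
    "write_report",
    "desikan_66_labels",
]


def _check_finite(df: pd.DataFrame, path) -> None:
    bad = np.argwhere(~np.isfinite(df.to_numpy(dtype=float)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-finite value at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )


def read_matrix(path, role: str = "covariance", labels=None) -> ConnectivityMatrix:
    """Read a labelled symmetric matrix from tab-delimited text.

    Row and column labels must agree as sets; if ``labels`` is given the
    matrix is reordered into that reference order on read.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        if set(df.index) != set(df.columns):
            raise ValueError(f"{path}: row and column labels differ")
        df = df.loc[df.columns, df.columns]
    _check_finite(df, path)
    m = ConnectivityMatrix(df.to_numpy(dtype=float), tuple(df.columns), role)
    if labels is not None:
        m = m.reordered(labels)
    return m


def write_matrix(m: ConnectivityMatrix, path) -> None:
    df = pd.DataFrame(m.values, index=list(m.labels), columns=list(m.labels))
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_envelopes(path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a T x p envelope matrix (header row of region labels)."""
    df = pd.read_csv(path, sep="\t")
    _check_finite(df, path)
    return df.to_numpy(dtype=float), tuple(str(c) for c in df.columns)


def write_envelopes(X, labels, path) -> None:
    pd.DataFrame(np.asarray(X), columns=list(labels)).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_cohort_manifest(path) -> list[SubjectRecord]:
    """Load a cohort from a manifest of per-subject file paths.

    Columns: ``id``, ``group``, ``envelopes``, ``fd``; paths are
    resolved relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"id", "group", "envelopes", "fd"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        X, env_labels = read_envelopes(path.parent / row.envelopes)
        fd = read_matrix(path.parent / row.fd, role="fiber_density",
                         labels=env_labels)
        records.append(
            SubjectRecord(id=str(row.id), group=str(row.group),
                          envelopes=X, fd=fd, true_theta=None)
        )
    return records


def write_cohort(records, outdir) -> Path:
    """Write per-subject envelope and FD files plus the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        env_name = f"{rec.id}_envelopes.tsv"
        fd_name = f"{rec.id}_fd.tsv"
        write_envelopes(rec.envelopes, rec.fd.labels, outdir / env_name)
        write_matrix(rec.fd, outdir / fd_name)
        rows.append({"id": rec.id, "group": rec.group,
                     "envelopes": env_name, "fd": fd_name})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(obj, path, seed: int | None = None, config=None) -> None:
    """Serialize a result to JSON with a provenance block."""
    from . import __version__

    payload = _jsonable(obj)
    config_json = json.dumps(_jsonable(config), sort_keys=True)
    provenance = {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest()[:16],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"provenance": provenance, "result": payload}, fh, indent=2)
        fh.write("\n")


_DESIKAN_33 = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
)


def desikan_66_labels() -> tuple[str, ...]:
    """The 66 cortical region labels (33 per hemisphere) of the
    Desikan-Killiany parcellation as used in MEG/DWI connectome studies.
    Shipped as a reference ordering; label sets are never enforced."""
    return tuple(f"lh.{r}" for r in _DESIKAN_33) + tuple(
        f"rh.{r}" for r in _DESIKAN_33
    )
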