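"""Plain-text serialization: labeled CSV matrices, CSD directories, posteriors.

Every coupling-matrix file carries the orientation convention in a comment
header (row = target, column = source) and readers reject files that declare
any other orientation — transposed matrices are the classic silent bug of
connectivity pipelines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .connectivity import EffectiveConnectivity
from .forward import CrossSpectralDensity, FCMatrix, FrequencyGrid
from .inversion import Posterior
from .regions import RegionSet
from .synthetic import Cohort, CohortConfig, SubjectTimeSeries

ORIENTATION_COMMENT = "# orientation: row=target, column=source"


class MatrixParseError(ValueError):
    pass


def write_matrix_csv(matrix: np.ndarray, labels: Sequence[str], path) -> None:
    """Labeled square matrix -> CSV with the orientation comment header."""
    path = Path(path)
    m = np.asarray(matrix, dtype=float)
    labels = list(labels)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(labels):
        raise ValueError("matrix must be square with one label per row/column")
    with open(path, "w") as fh:
        fh.write(ORIENTATION_COMMENT + "\n")
        fh.write("," + ",".join(labels) + "\n")
        for lab, row in zip(labels, m):
            fh.write(lab + "," + ",".join(repr(float(v)) for v in row) + "\n")


def read_matrix_csv(path) -> Tuple[np.ndarray, Tuple[str, ...]]:
    """Read a labeled square matrix, enforcing the orientation convention.

    Raises :class:`MatrixParseError` with a line number for label mismatches,
    non-square data, NaN cells, or a conflicting orientation declaration.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for k, line in enumerate(lines):
        if line.startswith("#"):
            if "orientation" in line.lower():
                normalized = line.replace(" ", "").lower()
                expected = ORIENTATION_COMMENT.replace(" ", "").lower()
                if normalized != expected:
                    raise MatrixParseError(
                        f"{path}:{k + 1}: orientation declaration {line!r} conflicts "
                        f"with the convention {ORIENTATION_COMMENT!r}"
                    )
            body_start = k + 1
        else:
            break
    body = lines[body_start:]
    if not body:
        raise MatrixParseError(f"{path}: no data rows")
    header = body[0].split(",")
    if header[0] != "":
        raise MatrixParseError(f"{path}:{body_start + 1}: first header cell must be empty")
    col_labels = header[1:]
    rows = []
    row_labels = []
    for k, line in enumerate(body[1:], start=body_start + 2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != len(col_labels) + 1:
            raise MatrixParseError(
                f"{path}:{k}: expected {len(col_labels) + 1} cells, got {len(cells)}"
            )
        row_labels.append(cells[0])
        try:
            vals = [float(v) for v in cells[1:]]
        except ValueError:
            raise MatrixParseError(f"{path}:{k}: non-numeric cell") from None
        if any(np.isnan(v) for v in vals):
            raise MatrixParseError(f"{path}:{k}: NaN cell")
        rows.append(vals)
    if row_labels != col_labels:
        raise MatrixParseError(
            f"{path}: row labels {row_labels} do not match column labels {col_labels}"
        )
    m = np.array(rows, dtype=float)
    if m.shape[0] != m.shape[1]:
        raise MatrixParseError(f"{path}: matrix is not square: {m.shape}")
    return m, tuple(col_labels)


def write_regions_csv(regions: RegionSet, path) -> None:
    rows = []
    for k, lab in enumerate(regions.labels):
        coord = regions.coordinates[k] if regions.coordinates else (np.nan,) * 3
        rows.append({"label": lab, "network": regions.networks[k],
                     "x": coord[0], "y": coord[1], "z": coord[2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_regions_csv(path) -> RegionSet:
    df = pd.read_csv(path)
    coords = None
    if {"x", "y", "z"} <= set(df.columns) and df[["x", "y", "z"]].notna().all().all():
        coords = tuple((r.x, r.y, r.z) for r in df.itertuples())
    return RegionSet(tuple(df["label"]), tuple(df["network"]), coords)


def write_timeseries_csv(ts: SubjectTimeSeries, path) -> None:
    df = pd.DataFrame(ts.data, columns=list(ts.labels))
    with open(path, "w") as fh:
        fh.write(f"# dt={ts.dt}\n")
        df.to_csv(fh, index=False)


def read_timeseries_csv(path) -> SubjectTimeSeries:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# dt="):
            raise MatrixParseError(f"{path}:1: missing '# dt=' header")
        dt = float(first.strip().split("=", 1)[1])
        df = pd.read_csv(fh)
    return SubjectTimeSeries(df.to_numpy(float), dt, tuple(df.columns))


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Cohort -> directory of per-subject CSVs plus regions, truth and config."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    write_regions_csv(cohort.regions, out / "regions.csv")
    for i, (ts, truth) in enumerate(zip(cohort.subjects, cohort.truths)):
        write_timeseries_csv(ts, out / f"subject_{i:03d}.csv")
        write_matrix_csv(truth.matrix, truth.regions.labels, out / "truth" / f"subject_{i:03d}.csv")
    write_matrix_csv(cohort.template.matrix, cohort.regions.labels, out / "truth" / "template.csv")
    with open(out / "config.json", "w") as fh:
        json.dump(cohort.config.to_dict(), fh, indent=2)


def read_cohort(in_dir) -> Cohort:
    src = Path(in_dir)
    with open(src / "config.json") as fh:
        config = CohortConfig.from_dict(json.load(fh))
    regions = read_regions_csv(src / "regions.csv")
    tmpl_m, tmpl_labels = read_matrix_csv(src / "truth" / "template.csv")
    if tmpl_labels != regions.labels:
        raise MatrixParseError("template labels do not match regions.csv")
    template = EffectiveConnectivity(tmpl_m, regions)
    subjects = []
    truths = []
    for i in range(config.n_subjects):
        subjects.append(read_timeseries_csv(src / f"subject_{i:03d}.csv"))
        m, _ = read_matrix_csv(src / "truth" / f"subject_{i:03d}.csv")
        truths.append(EffectiveConnectivity(m, regions))
    return Cohort(tuple(subjects), tuple(truths), template, config)


def write_csd(csd: CrossSpectralDensity, out_dir) -> None:
    """CSD -> directory with frequencies.csv and per-bin real/imag CSV pairs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"frequency_hz": csd.grid.frequencies}).to_csv(
        out / "frequencies.csv", index=False
    )
    for k in range(csd.grid.n_bins):
        write_matrix_csv(csd.values[k].real, csd.labels, out / f"real_{k:04d}.csv")
        write_matrix_csv(csd.values[k].imag, csd.labels, out / f"imag_{k:04d}.csv")


def read_csd(in_dir) -> CrossSpectralDensity:
    src = Path(in_dir)
    freqs = pd.read_csv(src / "frequencies.csv")["frequency_hz"].to_numpy(float)
    grid = FrequencyGrid(freqs)
    values = []
    labels = None
    for k in range(freqs.size):
        re, labels = read_matrix_csv(src / f"real_{k:04d}.csv")
        im, _ = read_matrix_csv(src / f"imag_{k:04d}.csv")
        values.append(re + 1j * im)
    return CrossSpectralDensity(np.array(values), grid, labels)


def write_posterior(post: Posterior, path) -> None:
    payload = {
        "names": list(post.names),
        "mean": post.mean.tolist(),
        "cov": post.cov.tolist(),
        "F": post.F,
        "settings": _jsonable(post.settings),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_posterior(path) -> Posterior:
    with open(path) as fh:
        payload = json.load(fh)
    return Posterior(
        tuple(payload["names"]),
        np.array(payload["mean"], dtype=float),
        np.array(payload["cov"], dtype=float),
        float(payload["F"]),
        payload.get("settings", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
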