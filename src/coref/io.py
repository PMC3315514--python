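"""Tabular input, validation and result serialization.

Input is a CSV/TSV with a header row, one column per variable and one row
per sample.  Two named columns become the test pair; the reference set is
either an explicit column list or all remaining numeric columns.  Cells
that are missing or non-numeric are hard errors reported with their
row/column coordinates — the permutation scheme requires complete rows, so
nothing is silently dropped.

A reference column that duplicates a test variable value-for-value is
refused unless explicitly forced, because including a test variable in the
reference data creates a correlation outlier that can destroy the power of
the test.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CoreferentialityResult, ReferenceSet, TestPair
from .exceptions import DegenerateDataError, DimensionError, ParameterError
from .simulate import SimulatedDataset

__all__ = [
    "read_table",
    "write_result",
    "read_result",
    "write_null_distribution",
    "write_grid",
    "write_dataset",
]

logger = logging.getLogger("coref")

#: columns of the power-grid TSV, in order
GRID_COLUMNS = [
    "method", "n", "k", "delta", "r_x", "mode", "n_noise_vars",
    "include_x1_in_y", "include_x2_in_y", "n_sims", "n_perm", "alpha",
    "power", "median_rc",
]


def _infer_sep(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _numeric_column(df: pd.DataFrame, col: str) -> np.ndarray:
    """Coerce one column to float, naming the first bad cell on failure."""
    s = pd.to_numeric(df[col], errors="coerce")
    bad = s.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DegenerateDataError(
            f"column {col!r}, row {row}: missing or non-numeric cell"
        )
    return s.to_numpy(dtype=float)


def read_table(
    path,
    x1: str,
    x2: str,
    ref_cols=None,
    delimiter: str | None = None,
    force_include_x_in_ref: bool = False,
):
    """Read and validate a sample table into (TestPair, ReferenceSet).

    Parameters
    ----------
    path : CSV or TSV file with a header row.
    x1, x2 : names of the two test-variable columns (must differ).
    ref_cols : explicit list of reference column names; by default all
        remaining numeric columns are used.
    delimiter : override the extension-inferred field separator.
    force_include_x_in_ref : retain reference columns that duplicate a
        test variable value-for-value (a loud warning is still emitted).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if x1 == x2:
        raise ParameterError("x1 and x2 must name different columns")
    df = pd.read_csv(path, sep=_infer_sep(path, delimiter))
    for name in (x1, x2):
        if name not in df.columns:
            raise ParameterError(f"column {name!r} not found in {path.name}")

    v1 = _numeric_column(df, x1)
    v2 = _numeric_column(df, x2)

    if ref_cols is None:
        # all remaining columns form the reference set; wholly textual
        # columns (sample IDs etc.) are skipped, but a numeric column with
        # a missing or malformed cell is a hard error, not a silent drop
        ref_cols = []
        for c in (c for c in df.columns if c not in (x1, x2)):
            parsed = pd.to_numeric(df[c], errors="coerce")
            bad = parsed.isna()
            if bad.all() and not df[c].isna().any():
                continue
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise DegenerateDataError(
                    f"column {c!r}, row {row}: missing or non-numeric cell"
                )
            ref_cols.append(c)
    else:
        ref_cols = list(ref_cols)
        for c in ref_cols:
            if c not in df.columns:
                raise ParameterError(f"reference column {c!r} not found in {path.name}")
        if x1 in ref_cols or x2 in ref_cols:
            raise ParameterError(
                "a test variable cannot be listed as its own reference column"
            )
    if not ref_cols:
        raise DimensionError("no reference columns found")

    cols, labels = [], []
    for c in ref_cols:
        v = _numeric_column(df, c)
        dup_of = "x1" if np.array_equal(v, v1) else ("x2" if np.array_equal(v, v2) else None)
        if dup_of is not None:
            msg = (
                f"reference column {c!r} duplicates test variable {dup_of} "
                "value-for-value; including a test variable in the reference "
                "data can abolish the power of the coreferentiality test"
            )
            if force_include_x_in_ref:
                warnings.warn(msg, stacklevel=2)
                logger.warning(msg)
            else:
                logger.warning("%s — column dropped (use force to keep it)", msg)
                continue
        cols.append(v)
        labels.append(c)
    if not cols:
        raise DimensionError("no reference columns remain after validation")

    pair = TestPair(x1=v1, x2=v2)
    ref = ReferenceSet(y=np.column_stack(cols), labels=tuple(labels))
    logger.info(
        "read %s: N=%d samples, k=%d reference columns", path.name, pair.n, ref.k
    )
    return pair, ref


def write_result(result: CoreferentialityResult, path, extra: dict | None = None):
    """Serialize one test result as JSON (summary statistics, not the full
    null distribution — see :func:`write_null_distribution`)."""
    payload = result.summary()
    if extra:
        payload.update(extra)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_result(path) -> dict:
    return json.loads(Path(path).read_text())


def write_null_distribution(result: CoreferentialityResult, path):
    """Write the full permutation null as a one-column TSV."""
    path = Path(path)
    pd.DataFrame({"null_rc": result.null_rc}).to_csv(path, sep="\t", index=False)
    return path


def write_grid(table: pd.DataFrame, path):
    """Write a power-study results table as TSV with the documented columns."""
    path = Path(path)
    cols = [c for c in GRID_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)
    return path


def write_dataset(ds: SimulatedDataset, path, sidecar: bool = True):
    """Write a simulated dataset as CSV (x1, x2, then reference columns)
    plus a JSON sidecar recording the generating spec and weights."""
    path = Path(path)
    df = pd.concat(
        [
            pd.DataFrame({"x1": ds.pair.x1, "x2": ds.pair.x2}),
            pd.DataFrame(ds.Y.y, columns=list(ds.Y.labels)),
        ],
        axis=1,
    )
    df.to_csv(path, index=False)
    if sidecar:
        spec = ds.spec
        meta = {
            "spec": {
                "n": spec.n, "k": spec.k, "delta": spec.delta, "r_x": spec.r_x,
                "mode": spec.mode, "n_noise_vars": spec.n_noise_vars,
                "include_x1_in_y": spec.include_x1_in_y,
                "include_x2_in_y": spec.include_x2_in_y,
                "sigma": spec.sigma, "seed": spec.seed,
            },
            "weights": [float(w) for w in ds.weights],
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")
    return path
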