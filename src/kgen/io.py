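"""Reading and writing phenotype tables, kinship matrices and factor directories.

Phenotype tables are tab- or whitespace-delimited text, one row per sample,
with the literal string ``NA`` (case-sensitive) marking a missing entry.  An
optional header row is auto-detected: a first row containing a token that is
neither numeric nor ``NA`` is treated as column names.

Kinship matrices come in two dialects: (a) dense whitespace-delimited text,
and (b) packed binary — row-major little-endian float64 with a JSON sidecar
(``<path>.json``) recording the dimension and a sha256 checksum, which round
trips bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix, PhenotypeMatrix

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_kinship",
    "write_kinship",
]

_SYMMETRY_ATOL = 1e-8


def _is_numeric_or_na(token: str) -> bool:
    if token == "NA":
        return True
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_phenotypes(path: str | Path) -> PhenotypeMatrix:
    """Parse a phenotype table; ``NA`` marks missing entries.

    Raises on ragged rows, on empty files, and on any token that is neither
    numeric nor exactly ``NA``, naming the offending row and column.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep=r"\s+", header=None, dtype=str, keep_default_na=False, na_values=[]
    )
    if raw.empty:
        raise ValueError(f"{path}: empty phenotype file")
    header_offset = 0
    first = raw.iloc[0]
    if first.isna().any():
        raise ValueError(f"{path}: ragged first row")
    if not all(_is_numeric_or_na(tok) for tok in first):
        raw = raw.iloc[1:].reset_index(drop=True)
        header_offset = 1
        if raw.empty:
            raise ValueError(f"{path}: phenotype file has a header but no data rows")
    values = np.empty(raw.shape, dtype=np.float64)
    for col in range(raw.shape[1]):
        tokens = raw.iloc[:, col]
        if tokens.isna().any():
            row = int(tokens.index[tokens.isna()][0])
            raise ValueError(
                f"{path}: ragged row {row + header_offset} (missing value in column {col})"
            )
        arr = tokens.to_numpy(dtype=object)
        is_na = arr == "NA"
        try:
            # numpy's str->float64 cast parses with correct rounding
            values[:, col] = np.where(is_na, "nan", arr).astype(np.float64)
        except ValueError:
            for row, tok in enumerate(arr):
                if not is_na[row] and not _is_numeric_or_na(str(tok)):
                    raise ValueError(
                        f"{path}: non-numeric token {tok!r} at row "
                        f"{row + header_offset}, column {col}"
                    ) from None
            raise
    return PhenotypeMatrix(values)


def write_phenotypes(pheno: PhenotypeMatrix | np.ndarray, path: str | Path) -> None:
    """Write a phenotype table with ``NA`` for missing entries (tab-delimited)."""
    values = pheno.values if isinstance(pheno, PhenotypeMatrix) else np.asarray(pheno)
    with open(path, "w") as fh:
        for row in values:
            fh.write(
                "\t".join("NA" if np.isnan(x) else repr(float(x)) for x in row) + "\n"
            )


def read_kinship(path: str | Path, binary: bool = False) -> KinshipMatrix:
    """Read a kinship matrix; errors on non-square or asymmetric input.

    Text dialect: dense whitespace-delimited, n rows of n values.  Binary
    dialect: packed float64 with JSON sidecar; the checksum is verified.
    """
    path = Path(path)
    if binary:
        meta = json.loads(Path(str(path) + ".json").read_text())
        data = path.read_bytes()
        if hashlib.sha256(data).hexdigest() != meta["sha256"]:
            raise IOError(f"{path}: checksum mismatch")
        n = int(meta["n"])
        values = np.frombuffer(data, dtype="<f8").reshape(n, n).copy()
    else:
        values = np.loadtxt(path, dtype=np.float64, ndmin=2)
        if values.shape[0] != values.shape[1]:
            raise ValueError(
                f"{path}: kinship matrix must be square, got {values.shape}"
            )
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > _SYMMETRY_ATOL:
        raise ValueError(
            f"{path}: kinship matrix asymmetric (max |K - K.T| = {asym:.3g})"
        )
    values = (values + values.T) / 2.0
    return KinshipMatrix(values)


def write_kinship(K: KinshipMatrix, path: str | Path, binary: bool = False) -> None:
    """Write a kinship matrix in the text or binary dialect."""
    path = Path(path)
    if binary:
        data = np.ascontiguousarray(K.values, dtype="<f8").tobytes()
        path.write_bytes(data)
        Path(str(path) + ".json").write_text(
            json.dumps({"n": K.n_samples, "sha256": hashlib.sha256(data).hexdigest()})
        )
    else:
        np.savetxt(path, K.values, fmt="%.17g")
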