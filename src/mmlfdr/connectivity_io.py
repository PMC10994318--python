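"""Reading, writing and transforming edge-wise connectivity data.

Connectivity studies compare two groups of subjects over all unordered
pairs of brain regions ("links").  Functional connectivity (FC) arrives as
Pearson correlations of BOLD time series, variance-stabilized by Fisher's
z transform; structural connectivity (SC) arrives as streamline fiber
counts, treated as Poisson and cube-root transformed toward normality.

Two in-memory containers are used throughout the package, both plain
:class:`pandas.DataFrame` objects with validated schemas:

``LinkTable``
    long format, one row per (link, subject):
    ``region1, region2, subject, group, fc_value, sc_value``.
``LinkStatistics``
    one row per link: ``region1, region2, tF, tS`` — the signed
    group-difference statistics for the FC and SC modalities.

Region pairs are canonicalized by sorting the two labels lexicographically,
so the unordered pair has a unique representation and FC/SC tables join
deterministically.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

LINK_TABLE_COLUMNS = ["region1", "region2", "subject", "group", "fc_value", "sc_value"]
LINK_STATS_COLUMNS = ["region1", "region2", "tF", "tS"]

#: absolute tolerance for symmetry of square-matrix input
MATRIX_SYMMETRY_ATOL = 1e-8


class FormatError(ValueError):
    """Malformed input data (asymmetry, unknown labels, duplicates)."""


@dataclass(frozen=True)
class RegionAtlas:
    """An ordered brain parcellation.

    Parameters
    ----------
    labels
        Unique, non-empty region names in matrix order.
    hemisphere
        Optional per-region tag, each one of ``"L"``, ``"R"``, ``"C"``.
    """

    labels: tuple[str, ...]
    hemisphere: tuple[str, ...] | None = None

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("an atlas needs at least 2 regions")
        if any(not lab for lab in labels):
            raise ValueError("region labels must be non-empty")
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if self.hemisphere is not None:
            hemi = tuple(self.hemisphere)
            object.__setattr__(self, "hemisphere", hemi)
            if len(hemi) != len(labels):
                raise ValueError("hemisphere tags must match label count")
            bad = set(hemi) - {"L", "R", "C"}
            if bad:
                raise ValueError(f"hemisphere tags must be L/R/C, got {sorted(bad)}")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @classmethod
    def read(cls, path: str | os.PathLike) -> "RegionAtlas":
        """Read an atlas file: one region per line, optional hemisphere column."""
        labels, hemis = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                labels.append(parts[0])
                if len(parts) > 1:
                    hemis.append(parts[1])
        hemisphere = tuple(hemis) if hemis else None
        return cls(tuple(labels), hemisphere)


def links_count(n_regions: int) -> int:
    """Number of unordered region pairs for an ``n_regions``-node parcellation.

    An 87-region atlas yields ``87 * 86 / 2 = 3741`` links; a 105-region
    atlas yields 5460.
    """
    if isinstance(n_regions, bool) or not isinstance(n_regions, (int, np.integer)):
        raise TypeError(f"n_regions must be an integer, got {n_regions!r}")
    if n_regions < 1:
        raise ValueError(f"n_regions must be >= 1, got {n_regions}")
    return n_regions * (n_regions - 1) // 2


def fisher_z(r):
    """Fisher's z transform ``arctanh(r)`` of a correlation in (-1, 1)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return out.item() if out.ndim == 0 else out


def sc_transform(count):
    """Cube-root transform of a non-negative fiber count."""
    count = np.asarray(count, dtype=float)
    if np.any(count < 0):
        raise ValueError("fiber counts must be non-negative")
    out = np.cbrt(count)
    return out.item() if out.ndim == 0 else out


def canonical_pairs(region1, region2) -> tuple[np.ndarray, np.ndarray]:
    """Order each (region1, region2) pair lexicographically."""
    r1 = np.asarray(region1, dtype=object)
    r2 = np.asarray(region2, dtype=object)
    if np.any(r1 == r2):
        raise FormatError("self-links (region1 == region2) are not valid links")
    swap = r1 > r2
    a = np.where(swap, r2, r1)
    b = np.where(swap, r1, r2)
    return a, b


def link_ids(df: pd.DataFrame) -> pd.Series:
    """Stable string id ``region1|region2`` for canonicalized pairs."""
    return df["region1"].astype(str) + "|" + df["region2"].astype(str)


# ---------------------------------------------------------------------------
# LinkTable
# ---------------------------------------------------------------------------

def validate_link_table(df: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize and validate a long-format link table.

    Returns a copy with sorted region pairs, integer group codes, and rows
    ordered by (link, subject).  Raises :class:`FormatError` on duplicate
    (link, subject) rows and :class:`ValueError` if a group is empty.
    """
    missing = [c for c in LINK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"link table is missing columns: {missing}")
    out = df.loc[:, LINK_TABLE_COLUMNS].copy()
    out["region1"], out["region2"] = canonical_pairs(out["region1"], out["region2"])
    out["group"] = out["group"].astype(int)
    if not set(out["group"].unique()) <= {0, 1}:
        raise FormatError("group must be coded 0 (control) / 1 (disease)")
    if out["group"].nunique() < 2:
        raise ValueError("both groups must be non-empty")
    for col in ("fc_value", "sc_value"):
        out[col] = out[col].astype(float)
    dup = out.duplicated(subset=["region1", "region2", "subject"])
    if dup.any():
        first = out.loc[dup.idxmax(), ["region1", "region2", "subject"]]
        raise FormatError(
            f"duplicate (link, subject) row: {tuple(first)}"
        )
    out = out.sort_values(["region1", "region2", "subject"], kind="stable")
    return out.reset_index(drop=True)


def _vectorize_upper(matrix: np.ndarray, atlas: RegionAtlas) -> pd.DataFrame:
    """Strict-upper-triangle vectorization (row-major over i < j)."""
    n = atlas.n_regions
    if matrix.shape != (n, n):
        raise FormatError(f"expected a {n}x{n} matrix, got {matrix.shape}")
    asym = np.max(np.abs(matrix - matrix.T))
    if asym > MATRIX_SYMMETRY_ATOL:
        raise FormatError(
            f"matrix asymmetric beyond tolerance: max |M - M.T| = {asym:.3g}"
        )
    iu, ju = np.triu_indices(n, k=1)
    labels = np.asarray(atlas.labels, dtype=object)
    return pd.DataFrame(
        {
            "region1": labels[iu],
            "region2": labels[ju],
            "value": matrix[iu, ju],
        }
    )


def read_link_table(
    path: str | os.PathLike,
    *,
    dialect: str = "long",
    atlas: RegionAtlas | None = None,
    sep: str | None = None,
    columns: dict[str, str] | None = None,
    apply_fisher_z: bool = False,
    apply_sc_transform: bool = False,
) -> pd.DataFrame:
    """Read a LinkTable from disk.

    Parameters
    ----------
    dialect
        ``"long"`` — a delimited file with the six LinkTable columns
        (rename via ``columns``, a mapping from file column -> standard
        name).  ``"matrix"`` — ``path`` is a manifest TSV with columns
        ``subject, group, fc_path, sc_path``, each path holding one
        whitespace/comma-delimited square matrix; requires ``atlas``.
    apply_fisher_z, apply_sc_transform
        Apply the variance-stabilizing transforms on read.  Defaults
        assume values are already transformed.
    """
    if dialect == "long":
        df = pd.read_csv(path, sep=sep if sep is not None else None, engine="python")
        if columns:
            df = df.rename(columns=columns)
        if atlas is not None:
            known = set(atlas.labels)
            unknown = (set(df["region1"]) | set(df["region2"])) - known
            if unknown:
                raise FormatError(f"unknown region labels: {sorted(unknown)[:5]}")
    elif dialect == "matrix":
        if atlas is None:
            raise ValueError("matrix dialect requires an atlas")
        manifest = pd.read_csv(path, sep=None, engine="python")
        need = {"subject", "group", "fc_path", "sc_path"}
        if not need <= set(manifest.columns):
            raise FormatError(f"manifest must have columns {sorted(need)}")
        base = os.path.dirname(os.fspath(path))
        rows = []
        for rec in manifest.itertuples(index=False):
            fc = _read_square_matrix(os.path.join(base, rec.fc_path))
            sc = _read_square_matrix(os.path.join(base, rec.sc_path))
            fc_long = _vectorize_upper(fc, atlas).rename(columns={"value": "fc_value"})
            sc_long = _vectorize_upper(sc, atlas).rename(columns={"value": "sc_value"})
            sub = fc_long.merge(sc_long, on=["region1", "region2"])
            sub["subject"] = rec.subject
            sub["group"] = rec.group
            rows.append(sub)
        df = pd.concat(rows, ignore_index=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if apply_fisher_z:
        df["fc_value"] = fisher_z(df["fc_value"].to_numpy())
    if apply_sc_transform:
        df["sc_value"] = sc_transform(df["sc_value"].to_numpy())
    return validate_link_table(df)


def _read_square_matrix(path: str) -> np.ndarray:
    with open(path) as fh:
        text = fh.read()
    delim = "," if "," in text.splitlines()[0] else None
    return np.loadtxt(io.StringIO(text), delimiter=delim)


def write_link_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a LinkTable as TSV (shortest exact float representation)."""
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LinkStatistics
# ---------------------------------------------------------------------------

def validate_link_statistics(df: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize and validate a per-link statistics table."""
    missing = [c for c in LINK_STATS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"link statistics table is missing columns: {missing}")
    out = df.loc[:, list(df.columns)].copy()
    out["region1"], out["region2"] = canonical_pairs(out["region1"], out["region2"])
    if out.duplicated(subset=["region1", "region2"]).any():
        raise FormatError("duplicate link in statistics table")
    for col in ("tF", "tS"):
        out[col] = out[col].astype(float)
        if not np.all(np.isfinite(out[col])):
            raise FormatError(f"non-finite values in {col}")
    out = out.sort_values(["region1", "region2"], kind="stable")
    return out.reset_index(drop=True)


def write_link_statistics(stats: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a LinkStatistics table as TSV (lossless round trip)."""
    stats = validate_link_statistics(stats)
    stats.to_csv(path, sep="\t", index=False)


def read_link_statistics(path: str | os.PathLike) -> pd.DataFrame:
    """Read a LinkStatistics TSV written by :func:`write_link_statistics`."""
    return validate_link_statistics(pd.read_csv(path, sep="\t"))
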