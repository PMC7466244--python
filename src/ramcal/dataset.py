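"""Spectral dataset containers and CSV I/O.

A Raman measurement campaign produces one intensity trace (counts per
second) per scan on a shared Raman-shift axis (cm^-1), plus a reference
table of element concentrations (ppm) per sample from the wet-chemistry
method.  This module holds both in plain numpy/pandas containers and
reads/writes them as CSV in two dialects:

wide
    first column is the shift axis, one column per scan with header
    ``<sample_id>:<replicate_id>``.
long
    records ``sample_id,replicate_id,shift,intensity``.

The axis is treated as data: spacing is not assumed uniform (uniformity
is checked only by operations that need it, e.g. the Savitzky-Golay
derivative).  Descending-axis files are accepted and re-ordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ELEMENTS = ("Ca", "Mg", "K", "Na", "Cu", "Mn", "Fe", "Zn")


class FormatError(ValueError):
    """Raised for malformed spectral or reference files."""


def _check_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise FormatError("axis must be a 1-D vector with >= 2 channels")
    d = np.diff(axis)
    if np.all(d > 0):
        return axis
    raise FormatError("axis must be strictly monotone without duplicates")


@dataclass
class RamanSpectrum:
    """A single scan: shift axis (cm^-1) and intensity (cps)."""

    axis: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.shape != self.intensity.shape:
            raise FormatError("axis and intensity must have equal length")
        if np.any(np.diff(self.axis) < 0):  # accept descending, re-order
            self.axis = self.axis[::-1]
            self.intensity = self.intensity[::-1]
        _check_axis(self.axis)
        if not np.all(np.isfinite(self.intensity)):
            raise FormatError("intensities must be finite")


@dataclass
class SpectralDataset:
    """Matrix of intensities (rows = scans or samples) on a shared axis.

    ``replicate_ids`` distinguishes multiple scans of the same sample;
    after :func:`average_replicates` there is one row per sample and the
    replicate ids are dropped.  ``meta`` is an optional per-sample table
    (formula id, powder concentration % w/w) indexed by sample_id.
    """

    axis: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    replicate_ids: list[str] | None = None
    meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.axis = _check_axis(np.asarray(self.axis, dtype=float))
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != self.axis.size:
            raise FormatError(
                f"row length {self.intensities.shape[1]} != axis length {self.axis.size}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.intensities.shape[0]:
            raise FormatError("one sample_id per intensity row required")
        if self.replicate_ids is not None:
            self.replicate_ids = [str(r) for r in self.replicate_ids]
            if len(self.replicate_ids) != len(self.sample_ids):
                raise FormatError("one replicate_id per row required")
        if not np.all(np.isfinite(self.intensities)):
            raise FormatError("intensities must be finite")

    @property
    def n_rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.size

    def with_intensities(self, intensities: np.ndarray) -> "SpectralDataset":
        """Copy with replaced intensity matrix (same axis/labels)."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))


def read_spectra_table(path, layout: str = "wide") -> SpectralDataset:
    """Read a CSV spectral table in the wide or long dialect.

    Rows are per-scan (replicates not yet averaged).  A descending axis
    is reversed, with the intensity rows re-ordered consistently.
    """
    if layout == "wide":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.shape[1] < 2:
            raise FormatError("wide table needs an axis column plus >= 1 scan column")
        axis = df.iloc[:, 0].to_numpy(dtype=float)
        inten = df.iloc[:, 1:].to_numpy(dtype=float).T
        sample_ids, replicate_ids = [], []
        for col in df.columns[1:]:
            sid, _, rid = str(col).rpartition(":")
            if not sid:
                sid, rid = rid, "1"
            sample_ids.append(sid)
            replicate_ids.append(rid)
    elif layout == "long":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"sample_id", "replicate_id", "shift", "intensity"}
        if not required.issubset(df.columns):
            raise FormatError(f"long table must have columns {sorted(required)}")
        wide = df.pivot_table(
            index=["sample_id", "replicate_id"], columns="shift",
            values="intensity", sort=True,
        )
        if wide.isna().any().any():
            raise FormatError("long table rows do not share a common axis")
        axis = wide.columns.to_numpy(dtype=float)
        inten = wide.to_numpy(dtype=float)
        sample_ids = [str(i[0]) for i in wide.index]
        replicate_ids = [str(i[1]) for i in wide.index]
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if axis.size >= 2 and np.all(np.diff(axis) < 0):
        axis = axis[::-1]
        inten = inten[:, ::-1]
    return SpectralDataset(axis, inten, sample_ids, replicate_ids)


def write_spectra_table(dataset: SpectralDataset, path, layout: str = "wide") -> None:
    """Write a dataset in the package's CSV dialect (round-trip exact)."""
    rids = dataset.replicate_ids or ["1"] * dataset.n_rows
    if layout == "wide":
        cols = {"shift": dataset.axis}
        for i, (sid, rid) in enumerate(zip(dataset.sample_ids, rids)):
            cols[f"{sid}:{rid}"] = dataset.intensities[i]
        pd.DataFrame(cols).to_csv(path, index=False)
    elif layout == "long":
        n = dataset.n_channels
        rows = pd.DataFrame({
            "sample_id": np.repeat(dataset.sample_ids, n),
            "replicate_id": np.repeat(rids, n),
            "shift": np.tile(dataset.axis, dataset.n_rows),
            "intensity": dataset.intensities.ravel(),
        })
        rows.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def average_replicates(dataset: SpectralDataset) -> SpectralDataset:
    """Arithmetic mean over each sample's scans; one row per sample.

    Idempotent: averaging an already-averaged dataset is the identity.
    Sample order follows first appearance in the input.
    """
    order: dict[str, list[int]] = {}
    for i, sid in enumerate(dataset.sample_ids):
        order.setdefault(sid, []).append(i)
    ids = list(order)
    mean = np.vstack([dataset.intensities[idx].mean(axis=0) for idx in order.values()])
    meta = None
    if dataset.meta is not None:
        meta = dataset.meta.loc[[s for s in ids if s in dataset.meta.index]]
    return SpectralDataset(dataset.axis, mean, ids, None, meta)


def crop_region(dataset: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Keep channels with lo <= shift <= hi (closed interval)."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    mask = (dataset.axis >= lo) & (dataset.axis <= hi)
    if not mask.any():
        raise ValueError(f"no channels in [{lo}, {hi}] cm^-1")
    return replace(
        dataset,
        axis=dataset.axis[mask],
        intensities=dataset.intensities[:, mask],
    )


def read_reference_table(path) -> pd.DataFrame:
    """Read a reference concentration CSV (sample_id, element, ppm[, repeatability])."""
    df = pd.read_csv(path)
    if not {"sample_id", "element", "ppm"}.issubset(df.columns):
        raise FormatError("reference table must have columns sample_id, element, ppm")
    bad = set(df["element"]) - set(ELEMENTS)
    if bad:
        raise FormatError(f"unknown elements {sorted(bad)}")
    if not np.all(np.isfinite(df["ppm"].to_numpy(dtype=float))):
        raise FormatError("concentrations must be finite")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def reference_vector(references: pd.DataFrame, element: str,
                     sample_ids: list[str]) -> np.ndarray:
    """Concentration vector for one element aligned to ``sample_ids``."""
    sub = references[references["element"] == element]
    lut = dict(zip(sub["sample_id"], sub["ppm"].astype(float)))
    missing = [s for s in sample_ids if s not in lut]
    if missing:
        raise KeyError(f"no {element} reference for samples {missing[:5]}")
    return np.array([lut[s] for s in sample_ids], dtype=float)
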