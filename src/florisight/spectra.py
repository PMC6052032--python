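"""Reflectance spectra: reading, dark correction, resampling and aggregation.

Reflectance is stored on the scale the instrument exported (fraction or
percent); every chromatic quantity downstream is invariant to a global scale
factor, so no unit normalisation is imposed.  The analysis window is
400-700 nm, the range relevant to platyrrhine cone vision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import (
    CoverageError,
    DataError,
    FormatError,
    GridMismatchError,
)

log = logging.getLogger(__name__)

#: Analysis window in nm.
WINDOW = (400.0, 700.0)

#: Metadata keys every spectrum carries.
META_KEYS = ("species", "item_kind", "part_label", "surface", "replicate_id")


@dataclass
class Spectrum:
    """A single reflectance spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array of float
        Wavelengths in nm, strictly increasing.
    values : array of float
        Reflectance readings, same length as ``wavelengths``.
    meta : dict
        Sample metadata; recognised keys are ``species``, ``item_kind``
        (``"flower"`` or ``"leaf"``), ``part_label``, ``surface``
        (``"upper"``, ``"lower"`` or ``"n/a"``) and ``replicate_id``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.values.shape:
            raise DataError("wavelengths and values must be 1-D arrays of equal length")
        if self.wavelengths.size < 2:
            raise DataError("a spectrum needs at least two samples")
        d = np.diff(self.wavelengths)
        if not np.all(d > 0):
            idx = int(np.argmax(d <= 0))
            raise DataError(f"wavelengths not strictly increasing at row {idx + 1}")
        if not np.all(np.isfinite(self.values)):
            raise DataError("non-finite reflectance values")

    # -- window helpers -------------------------------------------------
    def window_mask(self, window=WINDOW):
        lo, hi = window
        return (self.wavelengths >= lo) & (self.wavelengths <= hi)

    def covers(self, window=WINDOW) -> bool:
        lo, hi = window
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi

    @property
    def label(self) -> str:
        m = self.meta
        return "/".join(
            str(m.get(k, "?")) for k in ("species", "part_label", "surface", "replicate_id")
        )

    def copy_with(self, wavelengths=None, values=None, **meta_updates) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(
            self.wavelengths.copy() if wavelengths is None else wavelengths,
            self.values.copy() if values is None else values,
            meta,
        )


@dataclass
class SpectrumSet:
    """An ordered collection of spectra plus a processing log."""

    spectra: list = field(default_factory=list)
    provenance: list = field(default_factory=list)

    def __len__(self):
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]

    def note(self, message: str):
        self.provenance.append(message)
        log.debug("%s", message)

    def select(self, **meta) -> "SpectrumSet":
        """Subset by exact metadata match, preserving the provenance log."""
        kept = [
            s for s in self.spectra if all(s.meta.get(k) == v for k, v in meta.items())
        ]
        out = SpectrumSet(kept, list(self.provenance))
        out.note(f"select {meta}: {len(kept)}/{len(self.spectra)} kept")
        return out

    def common_grid(self) -> np.ndarray:
        if not self.spectra:
            raise DataError("empty spectrum set has no grid")
        g = self.spectra[0].wavelengths
        for s in self.spectra[1:]:
            if s.wavelengths.shape != g.shape or not np.allclose(s.wavelengths, g):
                raise GridMismatchError(
                    f"spectrum {s.label!r} is not on the common grid"
                )
        return g

    def map(self, fn) -> "SpectrumSet":
        out = SpectrumSet([fn(s) for s in self.spectra], list(self.provenance))
        return out


# ---------------------------------------------------------------------------
# reading


DEFAULT_LONG_COLUMNS = {
    "wavelength": "wavelength",
    "value": "value",
    "species": "species",
    "part": "part",
    "kind": "kind",
    "surface": "surface",
    "replicate": "replicate",
}


def read_spectra(path, dialect=None) -> SpectrumSet:
    """Read reflectance spectra from a CSV file.

    Two dialects are supported, selected by ``dialect["format"]``:

    ``"long"`` (default)
        Columns ``wavelength, value, species, part, kind, surface, replicate``
        (names remappable through ``dialect["columns"]``); one row per
        wavelength per sample.
    ``"wide"``
        A ``wavelength`` column followed by one column per sample.  Sample
        metadata comes from a sidecar CSV named in ``dialect["metadata"]``
        with columns ``sample, species, part, kind, surface, replicate``;
        without a sidecar each column name becomes the replicate id.

    Rows outside the 400-700 nm window are retained; the per-spectrum count
    of such rows is recorded under ``meta["n_outside_window"]``.
    """
    dialect = dict(dialect or {})
    fmt = dialect.get("format", "long")
    try:
        # "n/a" is a legitimate surface label, not a missing value
        df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    except (OSError, ValueError) as exc:  # pragma: no cover - passthrough
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if fmt == "long":
        out = _read_long(df, dialect)
    elif fmt == "wide":
        out = _read_wide(df, dialect)
    else:
        raise FormatError(f"unknown dialect format {fmt!r}")
    out.note(f"read {len(out)} spectra from {path} ({fmt} dialect)")
    return out


def _finish(wl, vals, meta) -> Spectrum:
    order_issue = np.diff(wl) <= 0
    if np.any(order_issue):
        idx = int(np.argmax(order_issue))
        raise DataError(
            f"wavelength column not strictly increasing at row {idx + 1} "
            f"(sample {meta.get('replicate_id')!r})"
        )
    s = Spectrum(wl, vals, meta)
    lo, hi = WINDOW
    n_out = int(np.sum((wl < lo) | (wl > hi)))
    s.meta["n_outside_window"] = n_out
    return s


def _read_long(df, dialect) -> SpectrumSet:
    cols = dict(DEFAULT_LONG_COLUMNS)
    cols.update(dialect.get("columns", {}))
    wcol, vcol = cols["wavelength"], cols["value"]
    if wcol not in df.columns:
        raise FormatError(f"missing wavelength column {wcol!r}")
    if vcol not in df.columns:
        raise FormatError(f"missing value column {vcol!r}")
    meta_cols = [
        (key, cols[k])
        for key, k in (
            ("species", "species"),
            ("item_kind", "kind"),
            ("part_label", "part"),
            ("surface", "surface"),
            ("replicate_id", "replicate"),
        )
        if cols[k] in df.columns
    ]
    group_cols = [c for _, c in meta_cols]
    out = SpectrumSet()
    groups = df.groupby(group_cols, sort=True, dropna=False) if group_cols else [((), df)]
    for key, sub in groups:
        if not isinstance(key, tuple):
            key = (key,)
        meta = {mk: kv for (mk, _), kv in zip(meta_cols, key)}
        meta.setdefault("surface", "n/a")
        sub = sub.sort_index()
        out.spectra.append(
            _finish(sub[wcol].to_numpy(float), sub[vcol].to_numpy(float), meta)
        )
    return out


def _read_wide(df, dialect) -> SpectrumSet:
    wcol = dialect.get("columns", {}).get("wavelength", "wavelength")
    if wcol not in df.columns:
        raise FormatError(f"missing wavelength column {wcol!r}")
    wl = df[wcol].to_numpy(float)
    meta_by_sample = {}
    sidecar = dialect.get("metadata")
    if sidecar is not None:
        mdf = pd.read_csv(sidecar)
        if "sample" not in mdf.columns:
            raise FormatError("sidecar metadata needs a 'sample' column")
        for _, row in mdf.iterrows():
            meta_by_sample[str(row["sample"])] = {
                "species": row.get("species"),
                "item_kind": row.get("kind"),
                "part_label": row.get("part"),
                "surface": row.get("surface", "n/a"),
                "replicate_id": row.get("replicate", row["sample"]),
            }
    out = SpectrumSet()
    for col in df.columns:
        if col == wcol:
            continue
        meta = meta_by_sample.get(
            str(col),
            {"species": None, "item_kind": None, "part_label": None,
             "surface": "n/a", "replicate_id": str(col)},
        )
        out.spectra.append(_finish(wl.copy(), df[col].to_numpy(float), dict(meta)))
    return out


def write_spectra(spectra: SpectrumSet, path) -> None:
    """Write a spectrum set as a long-format CSV (the default read dialect)."""
    frames = []
    for s in spectra:
        frames.append(
            pd.DataFrame(
                {
                    "wavelength": s.wavelengths,
                    "value": s.values,
                    "species": s.meta.get("species"),
                    "part": s.meta.get("part_label"),
                    "kind": s.meta.get("item_kind"),
                    "surface": s.meta.get("surface", "n/a"),
                    "replicate": s.meta.get("replicate_id"),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# processing


def dark_correct(s: Spectrum, window=WINDOW) -> Spectrum:
    """Subtract the minimum reading within the window from the whole spectrum.

    This is the baseline-drift correction applied to every field spectrum:
    the lowest reading between 400 and 700 nm is set to zero and all other
    readings shift with it.  Idempotent.
    """
    if not s.covers(window):
        raise CoverageError(
            f"spectrum {s.label!r} spans {s.wavelengths[0]:g}-{s.wavelengths[-1]:g} nm, "
            f"window {window} not covered"
        )
    floor = float(np.min(s.values[s.window_mask(window)]))
    return s.copy_with(values=s.values - floor, dark_corrected=True)


def resample(s: Spectrum, step: float = 1.0, window=WINDOW) -> Spectrum:
    """Linearly interpolate onto the regular 400..700 nm grid at ``step``.

    Endpoints are included.  Extrapolation is refused.
    """
    if not s.covers(window):
        raise CoverageError(
            f"cannot resample {s.label!r}: spans "
            f"{s.wavelengths[0]:g}-{s.wavelengths[-1]:g} nm"
        )
    lo, hi = window
    n = int(round((hi - lo) / step))
    grid = lo + step * np.arange(n + 1)
    vals = np.interp(grid, s.wavelengths, s.values)
    out = s.copy_with(wavelengths=grid, values=vals, resample_step=step)
    out.meta["n_outside_window"] = 0
    return out


def clip_nonnegative(s: Spectrum) -> Spectrum:
    """Clip negative readings (instrument noise near the dark floor) to 0.

    The number of clipped points is recorded in ``meta["n_clipped"]``.
    """
    n = int(np.sum(s.values < 0))
    if n == 0:
        return s
    return s.copy_with(values=np.clip(s.values, 0.0, None), n_clipped=n)


DEFAULT_REPLICATE_KEY = ("species", "item_kind", "part_label", "surface")


def average_replicates(spectra: SpectrumSet, key=DEFAULT_REPLICATE_KEY) -> SpectrumSet:
    """Average replicate spectra within each metadata key group.

    One mean spectrum per group; the group size is recorded under
    ``meta["n_replicates"]``.  All members must share a grid.
    """
    grid = spectra.common_grid()
    groups: dict = {}
    order: list = []
    for s in spectra:
        k = tuple(s.meta.get(f) for f in key)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(s)
    out = SpectrumSet(provenance=list(spectra.provenance))
    for k in order:
        members = groups[k]
        if not members:  # pragma: no cover - defensive
            out.note(f"empty replicate group {k}: skipped")
            continue
        mean_vals = np.mean([m.values for m in members], axis=0)
        meta = {f: v for f, v in zip(key, k)}
        meta["replicate_id"] = "mean"
        meta["n_replicates"] = len(members)
        out.spectra.append(Spectrum(grid.copy(), mean_vals, meta))
    out.note(f"averaged {len(spectra)} spectra into {len(out)} groups by {key}")
    return out


def mean_background(leaves: SpectrumSet) -> Spectrum:
    """Arithmetic mean of all leaf spectra: the heterogeneous leafy background.

    Upper and lower leaf surfaces of every species are pooled with equal
    weight, matching the use of a single mean leaf value as the adapting
    background in the discrimination model.
    """
    if len(leaves) == 0:
        raise DataError("cannot build a background from an empty leaf set")
    bad = [s.label for s in leaves if s.meta.get("item_kind") not in (None, "leaf")]
    if bad:
        raise DataError(f"non-leaf spectra in background set: {bad[:3]}")
    grid = leaves.common_grid()
    mean_vals = np.mean([s.values for s in leaves], axis=0)
    return Spectrum(
        grid.copy(),
        mean_vals,
        {
            "species": "pooled",
            "item_kind": "leaf",
            "part_label": "mean_background",
            "surface": "pooled",
            "replicate_id": "mean",
            "n_replicates": len(leaves),
        },
    )
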