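"""HDF5 container, CSV exports, and run-configuration documents.

Container layout (schema 1.0)::

    /axes/excitation_cm1   1D float64, attrs units="cm^-1"
    /axes/emission_cm1     1D float64, attrs units="cm^-1"
    /axes/t2_fs            1D float64, attrs units="fs"
    /data/cube             3D float64, order (excitation, emission, time)
    /meta                  group, attr "json" = JSON string with at least
                           schema_version; typically preset, temperature, seed
    /fit                   optional: taus, das (n_exp x n1 x n3), offset, ssr,
                           config (JSON string)
    /cls                   optional: t2_fs, slope, n_columns (+ fit attrs)
    /coherence             optional: frequency_cm1, amplitude, beat maps

CSV dialects: a 2D slice is written with header cell
``emission_cm1 \\ excitation_cm1`` (rows = emission, columns = excitation);
1D traces are plain ``column,value`` tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cls import CLSConfig, CLSFit, CLSTrace
from .coherence import BeatMap, CoherenceSpectrum, FSCConfig
from .core import Dataset2DES, FrequencyAxis, Map2D, TimeAxis
from .exceptions import SchemaError
from .globalfit import GlobalFitConfig, GlobalFitResult
from .simulate import DEFAULT_SEED

SCHEMA_VERSION = "1.0"
_SUPPORTED_SCHEMAS = {"1.0"}


# ---------------------------------------------------------------------------
# container


def write_container(
    path,
    ds: Dataset2DES,
    fit: GlobalFitResult | None = None,
    cls_trace: CLSTrace | None = None,
    cls_fit: CLSFit | None = None,
    spectrum: CoherenceSpectrum | None = None,
    beat_maps: list[BeatMap] | None = None,
) -> None:
    """Write a dataset (and any analysis results) to the HDF5 container."""
    with h5py.File(path, "w") as h5:
        axes = h5.create_group("axes")
        for name, values, units in (
            ("excitation_cm1", ds.excitation.values, "cm^-1"),
            ("emission_cm1", ds.emission.values, "cm^-1"),
            ("t2_fs", ds.time.values, "fs"),
        ):
            d = axes.create_dataset(name, data=values)
            d.attrs["units"] = units
        data = h5.create_group("data")
        data.create_dataset("cube", data=ds.cube)
        meta = dict(ds.meta)
        meta["schema_version"] = SCHEMA_VERSION
        h5.create_group("meta").attrs["json"] = json.dumps(meta, default=str)
    if fit is not None:
        write_fit(path, fit)
    if cls_trace is not None:
        write_cls(path, cls_trace, cls_fit)
    if spectrum is not None:
        write_coherence(path, spectrum, beat_maps)


def read_container(path) -> Dataset2DES:
    """Read and validate a dataset from the HDF5 container."""
    with h5py.File(path, "r") as h5:
        for group in ("axes", "data", "meta"):
            if group not in h5:
                raise SchemaError(f"container is missing the /{group} group")
        try:
            meta = json.loads(h5["meta"].attrs["json"])
        except KeyError as err:
            raise SchemaError("/meta is missing the 'json' attribute") from err
        version = meta.pop("schema_version", None)
        if version not in _SUPPORTED_SCHEMAS:
            raise SchemaError(f"unsupported schema_version {version!r}")
        axes = h5["axes"]
        for name in ("excitation_cm1", "emission_cm1", "t2_fs"):
            if name not in axes:
                raise SchemaError(f"container is missing /axes/{name}")
        if "cube" not in h5["data"]:
            raise SchemaError("container is missing /data/cube")
        exc = np.asarray(axes["excitation_cm1"])
        emi = np.asarray(axes["emission_cm1"])
        t2 = np.asarray(axes["t2_fs"])
        cube = np.asarray(h5["data"]["cube"])
    if cube.shape != (exc.size, emi.size, t2.size):
        raise SchemaError(
            f"cube shape {cube.shape} does not match axis lengths "
            f"({exc.size}, {emi.size}, {t2.size})"
        )
    return Dataset2DES(FrequencyAxis(exc), FrequencyAxis(emi), TimeAxis(t2),
                       cube, meta=meta)


def write_fit(path, result: GlobalFitResult) -> None:
    """Append (or replace) the /fit group of an existing container."""
    with h5py.File(path, "a") as h5:
        if "fit" in h5:
            del h5["fit"]
        g = h5.create_group("fit")
        g.create_dataset("taus_fs", data=result.taus)
        g.create_dataset("das", data=np.stack([m.amplitude for m in result.das]))
        if result.offset is not None:
            g.create_dataset("offset", data=result.offset.amplitude)
        g.create_dataset("ssr", data=result.ssr)
        g.attrs["config"] = result.config_json()
        g.attrs["n_pixels"] = result.n_pixels
        g.attrs["n_times"] = result.n_times


def read_fit(path) -> GlobalFitResult:
    """Read a stored global-fit result (requires the dataset in the same file)."""
    ds = read_container(path)
    with h5py.File(path, "r") as h5:
        if "fit" not in h5:
            raise SchemaError("container has no /fit group")
        g = h5["fit"]
        taus = np.asarray(g["taus_fs"])
        das = np.asarray(g["das"])
        offset = np.asarray(g["offset"]) if "offset" in g else None
        ssr = float(np.asarray(g["ssr"]))
        config = GlobalFitConfig(**json.loads(g.attrs["config"]))
        n_pixels = int(g.attrs.get("n_pixels", das[0].size))
        n_times = int(g.attrs.get("n_times", 0))
    cfg = GlobalFitConfig(
        n_exp=config.n_exp, t2_min=config.t2_min,
        tau_bounds=tuple(config.tau_bounds), n_starts=config.n_starts,
        include_offset=config.include_offset, tol=config.tol,
    )
    return GlobalFitResult(
        taus=taus,
        das=[Map2D(ds.excitation, ds.emission, m) for m in das],
        offset=Map2D(ds.excitation, ds.emission, offset) if offset is not None else None,
        ssr=ssr, config=cfg, time=ds.time, n_pixels=n_pixels, n_times=n_times,
        meta=ds.meta,
    )


def write_cls(path, trace: CLSTrace, fit: CLSFit | None = None) -> None:
    with h5py.File(path, "a") as h5:
        if "cls" in h5:
            del h5["cls"]
        g = h5.create_group("cls")
        g.create_dataset("t2_fs", data=trace.t2)
        g.create_dataset("slope", data=trace.slope)
        g.create_dataset("n_columns", data=trace.n_columns)
        if fit is not None:
            g.attrs["fit"] = json.dumps(asdict(fit))


def read_cls(path) -> tuple[CLSTrace, CLSFit | None]:
    with h5py.File(path, "r") as h5:
        if "cls" not in h5:
            raise SchemaError("container has no /cls group")
        g = h5["cls"]
        trace = CLSTrace(np.asarray(g["t2_fs"]), np.asarray(g["slope"]),
                         np.asarray(g["n_columns"]))
        fit = CLSFit(**json.loads(g.attrs["fit"])) if "fit" in g.attrs else None
    return trace, fit


def write_coherence(path, spectrum: CoherenceSpectrum,
                    beat_maps: list[BeatMap] | None = None) -> None:
    with h5py.File(path, "a") as h5:
        if "coherence" in h5:
            del h5["coherence"]
        g = h5.create_group("coherence")
        g.create_dataset("frequency_cm1", data=spectrum.frequency.values)
        g.create_dataset("amplitude", data=spectrum.amplitude)
        if beat_maps:
            bg = g.create_group("beat_maps")
            for bm in beat_maps:
                bg.create_dataset(f"{bm.nu:.1f}", data=bm.map.amplitude)


def read_coherence(path) -> CoherenceSpectrum:
    with h5py.File(path, "r") as h5:
        if "coherence" not in h5:
            raise SchemaError("container has no /coherence group")
        g = h5["coherence"]
        spec = CoherenceSpectrum(FrequencyAxis(np.asarray(g["frequency_cm1"])),
                                 np.asarray(g["amplitude"]))
    return spec


# ---------------------------------------------------------------------------
# CSV exports


def export_slice_csv(ds: Dataset2DES, t2: float, path) -> None:
    """One t2 slice as CSV: rows = emission, columns = excitation; the header
    cell is ``emission_cm1 \\ excitation_cm1``."""
    m = ds.map_at(t2)
    frame = pd.DataFrame(m.amplitude.T, index=m.emission.values,
                         columns=m.excitation.values)
    frame.index.name = "emission_cm1 \\ excitation_cm1"
    frame.to_csv(path)


# ---------------------------------------------------------------------------
# run configuration

#: Document schema of a run configuration (YAML or JSON); every key optional.
RUN_CONFIG_SCHEMA: dict = {
    "input": str,
    "output": str,
    "seed": int,
    "global_fit": {
        "n_exp": int, "t2_min": float, "tau_bounds": list,
        "n_starts": int, "include_offset": bool, "tol": float,
    },
    "cls": {
        "window": list, "column_method": str,
        "min_rel_intensity": float, "weighted": bool, "window_widen": float,
    },
    "fsc": {
        "window_function": str, "pad_factor": int,
        "normalize_input": bool, "aggregate": str,
    },
}


class RunConfig:
    """Validated bundle of per-stage configurations plus paths and seed."""

    def __init__(self, input: str | None = None, output: str | None = None,
                 seed: int = DEFAULT_SEED,
                 global_fit: GlobalFitConfig | None = None,
                 cls: CLSConfig | None = None,
                 fsc: FSCConfig | None = None):
        self.input = input
        self.output = output
        self.seed = seed
        self.global_fit = global_fit or GlobalFitConfig()
        self.cls = cls or CLSConfig()
        self.fsc = fsc or FSCConfig()

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        _validate_keys(doc, RUN_CONFIG_SCHEMA, "")
        gf = dict(doc.get("global_fit", {}))
        if "tau_bounds" in gf:
            gf["tau_bounds"] = tuple(gf["tau_bounds"])
        cl = dict(doc.get("cls", {}))
        if cl.get("window") is not None:
            cl["window"] = tuple(cl["window"])
        return cls(
            input=doc.get("input"), output=doc.get("output"),
            seed=doc.get("seed", DEFAULT_SEED),
            global_fit=GlobalFitConfig(**gf),
            cls=CLSConfig(**cl),
            fsc=FSCConfig(**doc.get("fsc", {})),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(doc, dict):
            raise SchemaError("run configuration must be a mapping")
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        return {
            "input": self.input, "output": self.output, "seed": self.seed,
            "global_fit": asdict(self.global_fit),
            "cls": asdict(self.cls),
            "fsc": asdict(self.fsc),
        }


def _validate_keys(doc: dict, schema: dict, prefix: str) -> None:
    for key, value in doc.items():
        if key not in schema:
            raise SchemaError(f"unknown configuration key {prefix + key!r}")
        sub = schema[key]
        if isinstance(sub, dict):
            if not isinstance(value, dict):
                raise SchemaError(f"configuration key {prefix + key!r} must be a mapping")
            _validate_keys(value, sub, prefix + key + ".")
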