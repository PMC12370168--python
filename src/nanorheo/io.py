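"""File formats: columnar text force curves and HDF5 force-volume containers.

Curves are plain-text columns (time_s, indentation_m or z_m+deflection_m,
force_N) with `# key = value` header metadata. Volumes are single-file HDF5
containers with a JSON metadata block carrying a semantic schema version;
readers refuse newer major versions. All stored units are SI.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .contact import ForceCurve
from .fvmap import ForceVolume

CURVE_SCHEMA = "1.0.0"
VOLUME_SCHEMA = "1.0.0"

_REQUIRED_META = ("t_tot_s", "I_max_s_frac")  # written automatically


class CurveFormatError(ValueError):
    """Malformed curve file: missing columns or invalid values."""


class SchemaError(ValueError):
    """Container metadata missing, corrupt, or from a newer major version."""


def _check_schema(found: str, expected: str) -> None:
    try:
        major = int(str(found).split(".")[0])
    except (ValueError, AttributeError):
        raise SchemaError(f"invalid schema version {found!r}")
    if major != int(expected.split(".")[0]):
        raise SchemaError(
            f"schema version {found} incompatible with reader {expected}"
        )


def write_curve(path: str, curve: ForceCurve, extra_meta: dict | None = None) -> None:
    """Write a force curve as columnar text with header metadata."""
    meta = {
        "schema": CURVE_SCHEMA,
        "t_tot_s": curve.t_tot,
        "t_max_s": curve.t_max,
        "I_max_m": curve.I_max,
    }
    for k, v in curve.meta.items():
        if isinstance(v, (int, float, str, bool)):
            meta[k] = v
    if extra_meta:
        meta.update(extra_meta)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} = {v!r}\n")
        fh.write("# columns: time_s indentation_m force_N velocity_m_s\n")
        for row in zip(curve.t, curve.I, curve.F, curve.v):
            fh.write(" ".join(np.format_float_scientific(x, precision=17)
                              for x in row) + "\n")


def _parse_header_value(raw: str):
    raw = raw.strip()
    for caster in (int, float):
        try:
            return caster(raw)
        except ValueError:
            pass
    if raw in ("True", "False"):
        return raw == "True"
    return raw.strip("'\"")


def read_curve(path: str) -> ForceCurve:
    """Read a columnar text force curve; inverse of write_curve.

    Accepts either an indentation_m column or the pair z_m + deflection_m,
    in which case indentation = z - deflection and the provenance flag
    `indentation_from_z` is set in meta.
    """
    meta: dict = {}
    columns: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("columns:"):
                    columns = body.split(":", 1)[1].split()
                elif "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = _parse_header_value(v)
                continue
            rows.append([float(x) for x in line.split()])
    if columns is None:
        raise CurveFormatError("missing '# columns:' header line")
    data = {name: np.array([r[i] for r in rows]) for i, name in enumerate(columns)}

    for required in ("time_s", "force_N"):
        if required not in data:
            raise CurveFormatError(f"missing required column {required!r}")
    t = data["time_s"]
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise CurveFormatError("time_s must be strictly increasing")
    F = data["force_N"]
    from_z = False
    if "indentation_m" in data:
        I = data["indentation_m"]
    elif "z_m" in data and "deflection_m" in data:
        I = data["z_m"] - data["deflection_m"]
        from_z = True
    else:
        raise CurveFormatError(
            "missing required column 'indentation_m' (or 'z_m' + 'deflection_m')"
        )
    v = data["velocity_m_s"] if "velocity_m_s" in data else np.gradient(I, t)

    t_tot = float(meta.get("t_tot_s", t[-1]))
    i_peak = int(np.argmax(I))
    t_max = float(meta.get("t_max_s", t[i_peak]))
    I_max = float(meta.get("I_max_m", I[i_peak]))
    F_bar = float(np.trapezoid(F, t) / t_tot)
    v_bar = float(np.trapezoid(np.abs(v), t) / t_tot)
    curve_meta = {
        k: v2
        for k, v2 in meta.items()
        if k not in ("schema", "t_tot_s", "t_max_s", "I_max_m")
    }
    if from_z:
        curve_meta["indentation_from_z"] = True
    return ForceCurve(
        t=t, F=F, I=I, v=v,
        t_max=t_max, t_tot=t_tot, I_max=I_max,
        F_bar=F_bar, v_bar=v_bar, meta=curve_meta,
    )


def write_volume(path: str, fv: ForceVolume) -> None:
    """Write a force volume to a single HDF5 container."""
    meta = {
        "schema": VOLUME_SCHEMA,
        "t_tot_s": fv.t_tot,
        "theta_rad": fv.theta,
        "p": fv.p,
        "extra": {k: v for k, v in fv.meta.items()
                  if isinstance(v, (int, float, str, bool))},
    }
    with h5py.File(path, "w") as h5:
        h5.attrs["kind"] = "nanorheo-volume"
        h5.attrs["metadata"] = json.dumps(meta)
        h5.create_dataset("t", data=fv.t)
        h5.create_dataset("F", data=fv.F)
        h5.create_dataset("I", data=fv.I)
        h5.create_dataset("height", data=fv.height)
        h5.create_dataset("I_max", data=fv.I_max)


def read_volume(path: str, row_block: int | None = None) -> ForceVolume:
    """Read a force-volume container; inverse of write_volume.

    `row_block` streams the 3-D arrays in blocks of that many rows
    (constant memory in ny); the result is identical to a whole-file load.
    """
    with h5py.File(path, "r") as h5:
        if h5.attrs.get("kind") != "nanorheo-volume":
            raise SchemaError("not a nanorheo force-volume container")
        try:
            meta = json.loads(h5.attrs["metadata"])
        except (KeyError, json.JSONDecodeError) as exc:
            raise SchemaError(f"corrupted metadata block: {exc}") from exc
        if "schema" not in meta:
            raise SchemaError("metadata missing schema version")
        _check_schema(meta["schema"], VOLUME_SCHEMA)

        ny = h5["t"].shape[0]
        if row_block is None or row_block >= ny:
            t = h5["t"][...]
            F = h5["F"][...]
            I = h5["I"][...]
        else:
            t = np.empty(h5["t"].shape)
            F = np.empty(h5["F"].shape)
            I = np.empty(h5["I"].shape)
            for lo in range(0, ny, row_block):
                hi = min(lo + row_block, ny)
                t[lo:hi] = h5["t"][lo:hi]
                F[lo:hi] = h5["F"][lo:hi]
                I[lo:hi] = h5["I"][lo:hi]
        height = h5["height"][...]
        I_max = h5["I_max"][...]
    return ForceVolume(
        t=t, F=F, I=I, height=height, I_max=I_max,
        t_tot=float(meta["t_tot_s"]), theta=float(meta["theta_rad"]),
        p=float(meta["p"]), meta=dict(meta.get("extra", {})),
    )


def write_map_tsv(prefix: str, nmap) -> list[str]:
    """Write NanomechMap channels as per-channel TSV matrices."""
    paths = []
    for name, arr in (
        ("E0_pa", nmap.E0),
        ("gamma", nmap.gamma),
        ("height_m", nmap.height),
        ("quality", nmap.quality),
    ):
        p = f"{prefix}.{name}.tsv"
        np.savetxt(p, arr, delimiter="\t", fmt="%.10e")
        paths.append(p)
    return paths
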