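"""Readers, writers and report formatting.

Tabular data travels as CSV with a ``time_h`` column, one column per acyl
position in migration-path order, and the hydrolyzed sink last.  Schemes,
rate sets and mechanism specifications travel as JSON.  Every file written
by the package starts with a provenance comment header (version, seed,
configuration hash); readers skip ``#`` comment lines.

Rates are always labeled with an explicit unit (h^-1 in kinetics files,
s^-1 in mechanism tables), never bare.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .fitting import FitResult
from .mechanism import Conditions, MechanismSpec, MigrationStep, StepRates
from .network import MigrationScheme, RateSet, TimeCourse

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "scheme_to_dict",
    "scheme_from_dict",
    "rates_to_dict",
    "rates_from_dict",
    "load_config",
    "save_config",
    "mechanism_from_dict",
    "load_mechanism",
    "report_fit",
    "provenance_header",
]

TIME_COLUMN = "time_h"

#: Row sums further than this from 1 trigger a warning on read
#: (observed integrals are referenced independently, so sums drift).
SUM_WARN_TOL = 0.02


def _config_hash(payload) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def provenance_header(seed=None, config=None) -> str:
    parts = [f"acylmig v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_sha1={_config_hash(config)}")
    return "# " + ", ".join(parts)


def write_timecourse(
    tc: TimeCourse, path: str | Path, seed=None
) -> None:
    """CSV with >= 6 significant digits and a provenance comment header."""
    path = Path(path)
    df = pd.DataFrame(tc.fractions, columns=list(tc.species))
    df.insert(0, TIME_COLUMN, tc.times)
    with path.open("w") as fh:
        fh.write(provenance_header(seed=seed, config=tc.meta) + "\n")
        if tc.meta:
            fh.write("# meta: " + json.dumps(tc.meta, default=str) + "\n")
        df.to_csv(fh, index=False, float_format="%.8g")


def read_timecourse(
    path: str | Path, observed: bool = True
) -> TimeCourse:
    """Parse and validate a time-course CSV.

    Rows are sorted by time.  For observed data, fractions may stray outside
    [0, 1] by at most 0.05 (integral noise); larger excursions, duplicated
    times, missing columns or non-numeric cells raise
    :class:`~acylmig.errors.ValidationError`.  Row sums deviating from 1 by
    more than 0.02 are accepted with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if TIME_COLUMN not in df.columns:
        raise ValidationError(f"{path}: missing required column {TIME_COLUMN!r}")
    species = [c for c in df.columns if c != TIME_COLUMN]
    if len(species) < 2:
        raise ValidationError(f"{path}: need >= 2 species columns")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValidationError(f"{path}: non-numeric values in column {col!r}")
    if df[TIME_COLUMN].duplicated().any():
        raise ValidationError(f"{path}: duplicated time points")
    df = df.sort_values(TIME_COLUMN, kind="stable").reset_index(drop=True)
    fractions = df[species].to_numpy(dtype=float)
    sums = fractions.sum(axis=1)
    bad = np.abs(sums - 1.0) > SUM_WARN_TOL
    if observed and bad.any():
        warnings.warn(
            f"{path}: {int(bad.sum())} rows have species fractions summing "
            f"more than {SUM_WARN_TOL} away from 1",
            stacklevel=2,
        )
    return TimeCourse(
        times=df[TIME_COLUMN].to_numpy(dtype=float),
        fractions=fractions,
        species=tuple(species),
        meta={"path": str(path)},
        observed=observed,
    )


# ---------------------------------------------------------------- JSON config


def scheme_to_dict(scheme: MigrationScheme) -> dict:
    return {
        "positions": list(scheme.positions),
        "hydrolysis": list(scheme.hydrolysis),
        "sink": scheme.sink,
        "start": scheme.start,
    }


def scheme_from_dict(d: dict) -> MigrationScheme:
    try:
        return MigrationScheme(
            positions=tuple(d["positions"]),
            hydrolysis=tuple(d["hydrolysis"]),
            sink=d.get("sink", "hydrolyzed"),
            start=d.get("start"),
        )
    except KeyError as exc:
        raise ValidationError(f"scheme config missing key {exc}") from None


def rates_to_dict(rates: RateSet) -> dict:
    d = {
        "unit": "h^-1",
        "k_fwd": list(rates.k_fwd),
        "k_bwd": list(rates.k_bwd),
        "k_hyd_secondary": rates.k_hyd_secondary,
    }
    if rates.k_hyd_primary is not None:
        d["k_hyd_primary"] = rates.k_hyd_primary
    return d


def rates_from_dict(d: dict) -> RateSet:
    unit = d.get("unit", "h^-1")
    if unit not in ("h^-1", "1/h"):
        raise ValidationError(f"kinetics rate tables must be in h^-1, got {unit!r}")
    try:
        return RateSet(
            k_fwd=tuple(d["k_fwd"]),
            k_bwd=tuple(d["k_bwd"]),
            k_hyd_secondary=d.get("k_hyd_secondary", 0.0),
            k_hyd_primary=d.get("k_hyd_primary"),
        )
    except KeyError as exc:
        raise ValidationError(f"rate config missing key {exc}") from None


def save_config(
    path: str | Path,
    scheme: MigrationScheme,
    rates: RateSet | None = None,
    seed=None,
) -> None:
    payload: dict = {"scheme": scheme_to_dict(scheme)}
    if rates is not None:
        payload["rates"] = rates_to_dict(rates)
    payload["provenance"] = {
        "version": __version__,
        "seed": seed,
        "config_sha1": _config_hash(payload["scheme"]),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_config(path: str | Path) -> tuple[MigrationScheme, RateSet | None]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    scheme = scheme_from_dict(payload.get("scheme", payload))
    rates = None
    if "rates" in payload:
        rates = rates_from_dict(payload["rates"])
        if rates.n_edges != scheme.n_edges:
            raise ValidationError(
                f"{path}: rate set has {rates.n_edges} edges but scheme "
                f"needs {scheme.n_edges}"
            )
    return scheme, rates


def _track_from_dict(d: dict, conditions: Conditions):
    if {"fwd", "rev"} <= d.keys():
        return (float(d["fwd"]), float(d["rev"]))
    if {"ka", "k_minus_a", "kb", "k_minus_b"} <= d.keys():
        return StepRates(
            ka=d["ka"],
            k_minus_a=d["k_minus_a"],
            kb=d["kb"],
            k_minus_b=d["k_minus_b"],
        )
    if {"dg_a", "dg_minus_a", "dg_b", "dg_minus_b"} <= d.keys():
        return StepRates.from_barriers(
            d["dg_a"], d["dg_minus_a"], d["dg_b"], d["dg_minus_b"], conditions
        )
    raise ValidationError(
        "each mechanism track needs either composite {fwd, rev}, elementary "
        "rates {ka, k_minus_a, kb, k_minus_b}, or barriers {dg_a, ...}"
    )


def mechanism_from_dict(d: dict) -> MechanismSpec:
    conditions = Conditions(
        temperature=d.get("temperature_K", 298.15),
        pH=d.get("pH", 8.0),
        kw=d.get("kw", 1e-14),
        kappa=d.get("kappa", 1.0),
    )
    steps = []
    try:
        for s in d["steps"]:
            steps.append(
                MigrationStep(
                    label=s.get("label", f"step{len(steps) + 1}"),
                    pka_fwd=s["pka_fwd"],
                    pka_bwd=s["pka_bwd"],
                    neutral=_track_from_dict(s["neutral"], conditions),
                    anionic=_track_from_dict(s["anionic"], conditions),
                )
            )
    except KeyError as exc:
        raise ValidationError(f"mechanism config missing key {exc}") from None
    return MechanismSpec(steps=tuple(steps), conditions=conditions)


def load_mechanism(path: str | Path) -> MechanismSpec:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    return mechanism_from_dict(payload)


# ------------------------------------------------------------------- reports


def _sci(x: float) -> str:
    return f"{x:.2E}"


def report_fit(result: FitResult, unit: str = "h^-1") -> str:
    """Fixed-width table: one row per constant, estimate +/- error, unit.

    Standard errors that could not be computed print as ``n.d.``;
    estimates pinned at the non-negativity bound are annotated.
    """
    lines = [f"{'constant':<8}{'estimate':>12}{'stderr':>14}  unit"]
    for name, value, se, hit in zip(
        result.param_names,
        result.values,
        result.standard_errors,
        result.bound_hits,
    ):
        se_txt = "n.d." if not np.isfinite(se) else "± " + _sci(se)
        note = "  [at bound]" if hit else ""
        lines.append(f"{name:<8}{_sci(value):>12}{se_txt:>14}  {unit}{note}")
    if not result.converged:
        lines.append("# WARNING: optimizer did not report convergence")
    if not result.identifiable:
        lines.append("# WARNING: parameters not identifiable (singular J^T J)")
    return "\n".join(lines)


def fit_to_frame(result: FitResult, unit: str = "h^-1") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "constant": result.param_names,
            "estimate": result.values,
            "stderr": result.standard_errors,
            "unit": unit,
            "at_bound": result.bound_hits,
        }
    )
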