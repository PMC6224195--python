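"""Table readers/writers and provenance metadata for the pipeline.

CSV is the canonical interchange format, JSON the report format.  Every
writer emits a small ``# key: value`` metadata header (seed, package
version) that the paired reader skips, so outputs are self-describing and
deterministic given the seed.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from pathlib import Path

import pandas as pd

from . import __version__
from .behavior import BehaviorCounts
from .consumption import Well, WellPlate
from .selection_model import AlleleTrajectory, FitnessEstimate

TRAJECTORY_COLUMNS = ["pair_label", "replicate_id", "generation", "proportion"]


class ValidationError(ValueError):
    """Input-table validation failure; the message names the offending rows."""


def _metadata_header(seed=None, extra=None):
    lines = [f"# compfit_version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def _read_table(path):
    """Read a delimited table, tolerating comma or tab dialects and
    ``#`` metadata/comment lines."""
    text = Path(path).read_text()
    body = "\n".join(
        ln for ln in text.splitlines() if not ln.startswith("#")
    ).strip()
    if not body:
        return pd.DataFrame()
    sep = "\t" if "\t" in body.splitlines()[0] else ","
    return pd.read_csv(_io.StringIO(body), sep=sep)


def read_trajectories(path):
    """Read a trajectory CSV into a list of :class:`AlleleTrajectory`.

    One row per measurement with columns pair_label, replicate_id,
    generation, proportion; extra columns are ignored.  Rows are grouped by
    (pair_label, replicate_id) and sorted by generation.  Validation
    failures report 1-based data row numbers.
    """
    df = _read_table(path)
    if df.empty:
        warnings.warn(f"{path}: empty trajectory file", stacklevel=2)
        return []
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s): {', '.join(missing)}")
    problems = []
    prop = pd.to_numeric(df["proportion"], errors="coerce")
    gen = pd.to_numeric(df["generation"], errors="coerce")
    for i in df.index:
        row = i + 1
        if pd.isna(prop[i]):
            problems.append(f"row {row}: non-numeric proportion "
                            f"{df['proportion'][i]!r}")
        elif not (0.0 <= prop[i] <= 1.0):
            problems.append(f"row {row}: proportion {prop[i]} outside [0, 1]")
        if pd.isna(gen[i]):
            problems.append(f"row {row}: non-numeric generation "
                            f"{df['generation'][i]!r}")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    df = df.assign(proportion=prop, generation=gen.astype(int))
    out = []
    for (pair, rep), grp in df.groupby(["pair_label", "replicate_id"],
                                       sort=True):
        grp = grp.sort_values("generation")
        out.append(AlleleTrajectory(
            pair_label=str(pair),
            replicate_id=str(rep),
            generations=tuple(grp["generation"]),
            proportions=tuple(grp["proportion"]),
        ))
    return out


def write_trajectories(trajectories, path, seed=None):
    """Write trajectories as the canonical CSV; lossless round trip."""
    rows = [
        {"pair_label": tr.pair_label, "replicate_id": tr.replicate_id,
         "generation": g, "proportion": repr(p)}
        for tr in trajectories
        for g, p in zip(tr.generations, tr.proportions)
    ]
    df = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_metadata_header(seed=seed))
        df.to_csv(fh, index=False)


def write_fit_report(estimates: dict, path_base, seed=None):
    """Write fitness estimates keyed by pair label as CSV and JSON.

    ``path_base`` gets ``.csv`` and ``.json`` suffixes appended (an existing
    suffix is stripped).  Returns the two paths written.
    """
    base = Path(path_base)
    if base.suffix in (".csv", ".json"):
        base = base.with_suffix("")
    rows = []
    for pair, est in estimates.items():
        d = est.to_dict()
        d["pair_label"] = pair
        rows.append(d)
    cols = ["pair_label", "w_hat", "log_w_hat", "s_hat", "ci_low", "ci_high",
            "ci_level", "ci_scale", "n_replicates", "n_points_total", "method"]
    df = pd.DataFrame(rows, columns=cols)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")
    with open(csv_path, "w") as fh:
        fh.write(_metadata_header(seed=seed))
        df.to_csv(fh, index=False)
    payload = {
        "metadata": {"compfit_version": __version__, "seed": seed},
        "estimates": {pair: est.to_dict() for pair, est in estimates.items()},
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return csv_path, json_path


def read_droplet_counts(path):
    """Read a droplet CSV: sample_id, channel_A_positive, channel_a_positive,
    total_droplets.  Returns a dict sample_id -> DropletCounts."""
    from .ddpcr import DropletCounts

    df = _read_table(path)
    required = ["sample_id", "channel_A_positive", "channel_a_positive",
                "total_droplets"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s): {', '.join(missing)}")
    return {
        str(r.sample_id): DropletCounts(
            n_pos_A=int(r.channel_A_positive),
            n_pos_a=int(r.channel_a_positive),
            n_total=int(r.total_droplets),
        )
        for r in df.itertuples()
    }


def read_plate(path, assay="plate_gfp"):
    """Read a consumption-plate CSV into a :class:`WellPlate`.

    plate_gfp dialect: well_id, role, signal_t0, signal_t1.
    liquid_od dialect: well_id, day, od600 (role optional, default test).
    """
    df = _read_table(path)
    if assay == "plate_gfp":
        required = ["well_id", "role", "signal_t0", "signal_t1"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(
                f"{path}: missing required column(s): {', '.join(missing)}")
        wells = [
            Well(well_id=str(r.well_id), role=str(r.role),
                 signal_t0=float(r.signal_t0), signal_t1=float(r.signal_t1))
            for r in df.itertuples()
        ]
        return WellPlate(wells=tuple(wells), assay="plate_gfp")
    if assay == "liquid_od":
        required = ["well_id", "day", "od600"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(
                f"{path}: missing required column(s): {', '.join(missing)}")
        wells = []
        for wid, grp in df.groupby("well_id", sort=True):
            series = tuple(sorted(
                (int(d), float(o)) for d, o in zip(grp["day"], grp["od600"])
            ))
            wells.append(Well(well_id=str(wid), role="test",
                              od_series=series))
        return WellPlate(wells=tuple(wells), assay="liquid_od")
    raise ValueError(f"unknown assay {assay!r}")


def write_plate(plate: WellPlate, path, seed=None):
    """Write a plate_gfp WellPlate as its canonical CSV."""
    rows = [
        {"well_id": w.well_id, "role": w.role,
         "signal_t0": repr(w.signal_t0), "signal_t1": repr(w.signal_t1)}
        for w in plate.wells
    ]
    df = pd.DataFrame(rows, columns=["well_id", "role", "signal_t0",
                                     "signal_t1"])
    with open(path, "w") as fh:
        fh.write(_metadata_header(seed=seed))
        df.to_csv(fh, index=False)


def read_behavior_counts(path):
    """Read a behavior CSV: strain, condition, n_scored, n_positive,
    denominator_kind.  Returns a list of BehaviorCounts."""
    df = _read_table(path)
    required = ["strain", "condition", "n_scored", "n_positive",
                "denominator_kind"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s): {', '.join(missing)}")
    return [
        BehaviorCounts(
            strain=str(r.strain), condition=str(r.condition),
            n_scored=int(r.n_scored), n_positive=int(r.n_positive),
            denominator_kind=str(r.denominator_kind),
        )
        for r in df.itertuples()
    ]


def write_provenance(path, seed, inputs=None, config=None):
    """Write a machine-readable provenance record for one pipeline run."""
    record = {
        "compfit_version": __version__,
        "seed": seed,
        "inputs": [str(p) for p in (inputs or [])],
        "config": config or {},
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return record
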