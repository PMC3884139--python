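"""Readers/writers for the panel CSV dialect, model-configuration JSON and
run manifests.

Panel CSV columns: ``subject``, optional ``cluster`` and ``unit``, ``time``,
``state`` (a state label, a comma-joined set, or ``*`` for fully unknown),
``exact`` (0/1) and any further columns taken as covariates.  The round trip
read -> write -> read is exact.
"""
from __future__ import annotations

import hashlib
import json
import time as _time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .model_core import (
    BaselineDef,
    DerivedBaselineDef,
    FrailtySpec,
    ModelSpec,
    SpecificationError,
    StateGraph,
    Term,
    TransitionModel,
)
from .panel_likelihood import ObservationRecord, PanelData, Subject

__all__ = [
    "read_panel_csv",
    "write_panel_csv",
    "spec_to_dict",
    "spec_from_dict",
    "load_spec",
    "save_spec",
    "write_manifest",
]

_RESERVED = ("subject", "cluster", "unit", "entry", "time", "state", "exact")


class PanelFormatError(ValueError):
    pass


def read_panel_csv(path, states: tuple[str, ...] | None = None) -> PanelData:
    """Read the documented panel CSV dialect into PanelData.

    ``states`` (when given) is used to validate state labels and to expand
    the ``*`` wildcard; otherwise labels are taken at face value.
    """
    df = pd.read_csv(path, dtype={"state": str})
    for col in ("subject", "time", "state"):
        if col not in df.columns:
            raise PanelFormatError(f"missing required column {col!r}")
    cov_cols = [c for c in df.columns if c not in _RESERVED]
    subjects = []
    for sid, grp in df.groupby("subject", sort=False):
        grp = grp.reset_index()
        times = grp["time"].to_numpy(dtype=float)
        for i in range(1, len(times)):
            if times[i] <= times[i - 1]:
                raise PanelFormatError(
                    f"subject {sid}: non-increasing time at input row {int(grp['index'][i]) + 2}"
                )
        recs = []
        for i, row in grp.iterrows():
            raw = str(row["state"]).strip()
            if raw == "*":
                if states is None:
                    raise PanelFormatError("'*' state requires a known state list")
                st = tuple(states)
            else:
                st = tuple(s.strip() for s in raw.split(","))
            if states is not None:
                for s in st:
                    if s not in states:
                        raise PanelFormatError(
                            f"unknown state code {s!r} at input row {int(row['index']) + 2}"
                        )
            exact = bool(int(row["exact"])) if "exact" in grp.columns else False
            cov = {c: float(row[c]) for c in cov_cols if pd.notna(row[c])}
            recs.append(ObservationRecord(float(row["time"]), st, exact=exact, covariates=cov))
        cluster = grp["cluster"].iloc[0] if "cluster" in grp.columns else None
        unit = grp["unit"].iloc[0] if "unit" in grp.columns else None
        if cluster is not None and pd.isna(cluster):
            cluster = None
        if unit is not None and pd.isna(unit):
            unit = None
        entry = float(grp["entry"].iloc[0]) if "entry" in grp.columns else times[0]
        subjects.append(Subject(sid, recs, cluster=cluster, unit=unit, entry_time=entry))
    return PanelData(subjects)


def write_panel_csv(data: PanelData, path) -> None:
    rows = []
    cov_cols: list[str] = []
    for subj in data.subjects:
        for rec in subj.records:
            for c in rec.covariates:
                if c not in cov_cols:
                    cov_cols.append(c)
    for subj in data.subjects:
        for rec in subj.records:
            row: dict[str, Any] = {
                "subject": subj.id,
                "entry": subj.entry_time,
                "time": rec.time,
                "state": ",".join(rec.states),
                "exact": int(rec.exact),
            }
            if subj.cluster is not None:
                row["cluster"] = subj.cluster
            if subj.unit is not None:
                row["unit"] = subj.unit
            for c in cov_cols:
                if c in rec.covariates:
                    row[c] = rec.covariates[c]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model configuration JSON
# ---------------------------------------------------------------------------


def spec_to_dict(spec: ModelSpec) -> dict:
    baselines = {}
    for name, bd in spec.baselines.items():
        if isinstance(bd, DerivedBaselineDef):
            baselines[name] = {
                "derived": bd.rule,
                "sources": list(bd.sources),
                "n_num": bd.n_num,
                "k": bd.k,
                "offset_param": bd.offset_param,
            }
        else:
            baselines[name] = {"kind": bd.kind, "cutpoints": list(bd.cutpoints)}
    emission = None
    if spec.emission is not None:
        rows = []
        for row in spec.emission.entries:
            out_row = []
            for e in row:
                if isinstance(e, tuple) and e[0] == "logit":
                    out_row.append(
                        {"logit": [[t.covariate, t.label] for t in e[1]]}
                    )
                else:
                    out_row.append(e)
            rows.append(out_row)
        emission = {
            "hidden": list(spec.emission.hidden),
            "codes": list(spec.emission.codes),
            "entries": rows,
        }
    return {
        "states": list(spec.graph.states),
        "unobservable": sorted(spec.graph.unobservable),
        "transitions": [
            {
                "from": a,
                "to": b,
                "baseline": spec.transitions[(a, b)].baseline,
                "terms": [[t.covariate, t.label] for t in spec.transitions[(a, b)].terms],
            }
            for a, b in spec.graph.transitions
        ],
        "baselines": baselines,
        "constraints": {
            "equal": [list(g) for g in spec.equal],
            "fixed": dict(spec.fixed),
        },
        "emission": emission,
        "frailty": None
        if spec.frailty is None
        else {
            "theta_param": spec.frailty.theta_param,
            "quadrature_order": spec.frailty.quadrature_order,
        },
        "state_groups": {k: list(v) for k, v in spec.state_groups.items()},
        "initial_state": spec.initial_state,
        "metadata": dict(spec.metadata),
    }


def spec_from_dict(d: Mapping[str, Any]) -> ModelSpec:
    from .hidden_states import EmissionModel

    states = tuple(d["states"])
    trs = tuple((t["from"], t["to"]) for t in d["transitions"])
    graph = StateGraph(states, trs, unobservable=frozenset(d.get("unobservable", ())))
    baselines: dict[str, Any] = {}
    for name, bd in d["baselines"].items():
        if "derived" in bd:
            baselines[name] = DerivedBaselineDef(
                name,
                bd["derived"],
                tuple(bd["sources"]),
                n_num=bd.get("n_num", 1),
                k=bd.get("k", 1.0),
                offset_param=bd.get("offset_param"),
            )
        else:
            baselines[name] = BaselineDef(
                name, bd.get("kind", "constant"), tuple(bd.get("cutpoints", ()))
            )
    transitions = {}
    for t in d["transitions"]:
        tr = (t["from"], t["to"])
        transitions[tr] = TransitionModel(
            tr, t["baseline"], tuple(Term(c, l) for c, l in t.get("terms", ()))
        )
    emission = None
    if d.get("emission"):
        rows = []
        for row in d["emission"]["entries"]:
            out_row = []
            for e in row:
                if isinstance(e, dict) and "logit" in e:
                    out_row.append(("logit", tuple(Term(c, l) for c, l in e["logit"])))
                else:
                    out_row.append(e)
            rows.append(tuple(out_row))
        emission = EmissionModel(
            tuple(d["emission"]["hidden"]), tuple(d["emission"]["codes"]), tuple(rows)
        )
    frailty = None
    if d.get("frailty"):
        frailty = FrailtySpec(
            d["frailty"].get("theta_param", "theta"),
            d["frailty"].get("quadrature_order", 30),
        )
    cons = d.get("constraints", {})
    return ModelSpec(
        graph=graph,
        transitions=transitions,
        baselines=baselines,
        equal=tuple(tuple(g) for g in cons.get("equal", ())),
        fixed=dict(cons.get("fixed", {})),
        emission=emission,
        frailty=frailty,
        state_groups={k: tuple(v) for k, v in d.get("state_groups", {}).items()},
        initial_state=d.get("initial_state"),
        metadata=dict(d.get("metadata", {})),
    )


def load_spec(path) -> ModelSpec:
    with open(path) as fh:
        return spec_from_dict(json.load(fh))


def save_spec(spec: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(spec_to_dict(spec), fh, indent=2)


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------


def _file_hash(path) -> str | None:
    p = Path(path)
    if not p.exists():
        return None
    return hashlib.sha256(p.read_bytes()).hexdigest()[:16]


def write_manifest(out_path, seed=None, config=None, data=None, extra=None) -> dict:
    manifest = {
        "version": __version__,
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config_hash": _file_hash(config) if config else None,
        "data_hash": _file_hash(data) if data else None,
    }
    if extra:
        manifest.update(extra)
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2))
    return manifest
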