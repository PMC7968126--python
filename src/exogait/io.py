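"""Trial-bundle and session-artifact serialization.

A trial bundle is a directory of plain-text files, one CSV per stream
(``time_s`` plus channel columns with units in the header names), an
``events.csv`` ground-truth table, and a ``trial.json`` sidecar
echoing the full generator config, the seed, the sampling rates, the
config hash, and the package version.  Floats are serialized with
shortest-round-trip ``repr``, so a write/read cycle reproduces the
in-memory values exactly and reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .feedback import BiofeedbackState, StepRecord
from .synth import GaitGenConfig, GaitTrial, JOINTS, MUSCLES, SIDES

__all__ = [
    "write_trial",
    "read_trial",
    "write_session_outputs",
    "write_json",
]

STREAM_FILES = {
    "fsr": "fsr.csv",
    "markers": "markers.csv",
    "grf": "grf.csv",
    "emg": "emg.csv",
    "kinetics": "kinetics.csv",
    "exo": "exo_torque.csv",
}


def _df_to_csv(df: pd.DataFrame, path: Path) -> None:
    # %.17g guarantees exact float64 round-trips through text
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def write_json(obj: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_trial(trial: GaitTrial, outdir: str | Path) -> Path:
    """Write a trial bundle; returns the directory path."""
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)

    _df_to_csv(
        pd.DataFrame(
            {"time_s": trial.t_fsr,
             "fsr_left_v": trial.fsr["left"],
             "fsr_right_v": trial.fsr["right"]}
        ),
        d / STREAM_FILES["fsr"],
    )
    _df_to_csv(
        pd.DataFrame(
            {"time_s": trial.t_marker,
             "heel_y_left_m": trial.heel["left"],
             "heel_y_right_m": trial.heel["right"]}
        ),
        d / STREAM_FILES["markers"],
    )
    _df_to_csv(
        pd.DataFrame(
            {"time_s": trial.t_force,
             "grf_left_n": trial.grf["left"],
             "grf_right_n": trial.grf["right"]}
        ),
        d / STREAM_FILES["grf"],
    )
    emg_cols = {"time_s": trial.t_emg}
    for m in MUSCLES:
        for s in SIDES:
            emg_cols[f"{m}_{s}_mv"] = trial.emg[(m, s)]
            emg_cols[f"{m}_{s}_envelope_mv"] = trial.emg_envelope[(m, s)]
    _df_to_csv(pd.DataFrame(emg_cols), d / STREAM_FILES["emg"])

    kin_cols = {"time_s": trial.t_marker}
    for j in JOINTS:
        for s in SIDES:
            kin_cols[f"{j}_angle_{s}_deg"] = trial.angles[(j, s)]
            kin_cols[f"{j}_moment_{s}_nm"] = trial.moments[(j, s)]
    _df_to_csv(pd.DataFrame(kin_cols), d / STREAM_FILES["kinetics"])

    _df_to_csv(
        pd.DataFrame(
            {"time_s": trial.t_fsr,
             "left_nm": trial.exo_torque["left"],
             "right_nm": trial.exo_torque["right"]}
        ),
        d / STREAM_FILES["exo"],
    )
    _df_to_csv(trial.truth, d / "events.csv")

    write_json(
        {
            "config": trial.config.to_jsonable(),
            "config_hash": trial.config.config_hash(),
            "condition": trial.condition,
            "analysis_window_s": list(trial.analysis_window_s),
            "package_version": __version__,
        },
        d / "trial.json",
    )
    return d


def read_trial(bundle_dir: str | Path) -> GaitTrial:
    """Read a trial bundle written by :func:`write_trial`."""
    d = Path(bundle_dir)
    meta_path = d / "trial.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"not a trial bundle: missing {meta_path}")
    meta = json.loads(meta_path.read_text())
    config = GaitGenConfig.from_jsonable(meta["config"])

    def load(name: str) -> pd.DataFrame:
        p = d / STREAM_FILES[name]
        if not p.exists():
            raise FileNotFoundError(f"trial bundle missing stream file {p.name}")
        return pd.read_csv(p, float_precision="round_trip")

    fsr_df = load("fsr")
    markers = load("markers")
    grf_df = load("grf")
    emg_df = load("emg")
    kin = load("kinetics")
    exo = load("exo")
    truth = pd.read_csv(d / "events.csv", float_precision="round_trip")

    return GaitTrial(
        config=config,
        condition=meta.get("condition", "baseline"),
        t_fsr=fsr_df["time_s"].to_numpy(),
        fsr={s: fsr_df[f"fsr_{s}_v"].to_numpy() for s in SIDES},
        t_marker=markers["time_s"].to_numpy(),
        heel={s: markers[f"heel_y_{s}_m"].to_numpy() for s in SIDES},
        angles={(j, s): kin[f"{j}_angle_{s}_deg"].to_numpy()
                for j in JOINTS for s in SIDES},
        moments={(j, s): kin[f"{j}_moment_{s}_nm"].to_numpy()
                 for j in JOINTS for s in SIDES},
        t_force=grf_df["time_s"].to_numpy(),
        grf={s: grf_df[f"grf_{s}_n"].to_numpy() for s in SIDES},
        t_emg=emg_df["time_s"].to_numpy(),
        emg={(m, s): emg_df[f"{m}_{s}_mv"].to_numpy()
             for m in MUSCLES for s in SIDES},
        emg_envelope={(m, s): emg_df[f"{m}_{s}_envelope_mv"].to_numpy()
                      for m in MUSCLES for s in SIDES},
        exo_torque={s: exo[f"{s}_nm"].to_numpy() for s in SIDES},
        truth=truth,
        analysis_window_s=tuple(meta["analysis_window_s"]),
    )


def write_session_outputs(
    steps: list[StepRecord],
    timeline: list[BiofeedbackState],
    outdir: str | Path,
    session_meta: dict | None = None,
) -> tuple[Path, Path]:
    """Write ``steps.csv`` and ``feedback_timeline.csv`` (+ sidecar)."""
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    steps_df = pd.DataFrame(
        {
            "n": [s.index for s in steps],
            "side": [s.side for s in steps],
            "t_n_s": [s.contact_time_s for s in steps],
            "est_length_m": [s.est_length_m for s in steps],
        }
    )
    _df_to_csv(steps_df, d / "steps.csv")
    tl = pd.DataFrame(
        {
            "time_s": [st.time_s for st in timeline],
            "n_steps": [st.n_steps for st in timeline],
            "left_avg_m": [st.left_avg_m for st in timeline],
            "right_avg_m": [st.right_avg_m for st in timeline],
            "refreshed": [st.refreshed for st in timeline],
            "hit": [st.hit for st in timeline],
            "score": [st.score for st in timeline],
        }
    )
    _df_to_csv(tl, d / "feedback_timeline.csv")
    meta = {"package_version": __version__}
    if session_meta:
        meta.update(session_meta)
    write_json(meta, d / "session_meta.json")
    return d / "steps.csv", d / "feedback_timeline.csv"
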