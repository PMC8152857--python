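"""Reading and writing sessions in a documented plain-text layout.

Version 1 layout::

    session_dir/
      session.json              # format version, task timing, metadata
      pair_0000/
        events.csv              # trial_id, direction, delay_class, event times (ms)
        lfp_short.csv           # one row per short-delay trial: trial_id, s0, s1, ...
        lfp_long.csv
        lfp.json                # {"fs": 1000.0, "t0": 0.0}
        spikes.csv              # trial_id, spike_time_ms
        ground_truth.json       # generator labels (empty dict for recorded data)
      pair_0001/ ...

Within a delay class all trials share one trace length, so the LFP files
are rectangular.  Malformed files raise errors naming the file (and row
where applicable).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from .core import (AnalogTrace, Session, SessionPair, SpikeTrain, TaskTiming,
                   TrialEvents)

FORMAT_VERSION = "1"

_EVENT_COLS = ["trial_id", "direction", "delay_class", "t_start", "t_tc_on",
               "t_tc_off", "t_sc_on", "t_sc_off", "t_go", "t_move_on"]


def write_session(session: Session, out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"format_version": FORMAT_VERSION,
            "timing": dataclasses.asdict(session.timing),
            "meta": session.meta,
            "n_pairs": len(session.pairs)}
    (out_dir / "session.json").write_text(json.dumps(meta, indent=2))
    for pair in session.pairs:
        pdir = out_dir / f"pair_{pair.pair_id:04d}"
        pdir.mkdir(exist_ok=True)
        ev_df = pd.DataFrame([{c: getattr(ev, c) for c in _EVENT_COLS}
                              for ev in pair.events])
        ev_df.to_csv(pdir / "events.csv", index=False)
        for delay_class in ("short", "long"):
            tids = [ev.trial_id for ev in pair.events
                    if ev.delay_class == delay_class]
            if not tids:
                continue
            rows = [np.concatenate([[tid], pair.lfps[tid].samples])
                    for tid in tids]
            arr = np.array(rows)
            hdr = "trial_id," + ",".join(f"s{i}" for i in range(arr.shape[1] - 1))
            np.savetxt(pdir / f"lfp_{delay_class}.csv", arr, delimiter=",",
                       header=hdr, comments="", fmt="%.6g")
        fs = pair.lfps[pair.events[0].trial_id].fs if pair.events else 1000.0
        (pdir / "lfp.json").write_text(json.dumps({"fs": fs, "t0": 0.0}))
        spike_rows = []
        for ev in pair.events:
            for t in pair.spikes[ev.trial_id].spike_times:
                spike_rows.append((ev.trial_id, t))
        pd.DataFrame(spike_rows, columns=["trial_id", "spike_time_ms"]
                     ).to_csv(pdir / "spikes.csv", index=False)
        (pdir / "ground_truth.json").write_text(
            json.dumps(pair.ground_truth, indent=2))
    return out_dir


def _require_cols(df: pd.DataFrame, cols: List[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_session(in_dir: Path) -> Session:
    in_dir = Path(in_dir)
    meta_path = in_dir / "session.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"{meta_path} not found; not a session directory")
    meta = json.loads(meta_path.read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"{meta_path}: unsupported format version "
                         f"{meta.get('format_version')!r}")
    timing = TaskTiming(**meta["timing"])
    pairs = []
    for pdir in sorted(in_dir.glob("pair_*")):
        pair_id = int(pdir.name.split("_")[1])
        ev_path = pdir / "events.csv"
        ev_df = pd.read_csv(ev_path)
        _require_cols(ev_df, _EVENT_COLS, ev_path)
        events = []
        for i, row in ev_df.iterrows():
            try:
                events.append(TrialEvents(
                    int(row.trial_id), int(row.direction), str(row.delay_class),
                    float(row.t_start), float(row.t_tc_on), float(row.t_tc_off),
                    float(row.t_sc_on), float(row.t_sc_off), float(row.t_go),
                    float(row.t_move_on)))
            except (ValueError, TypeError) as e:
                raise ValueError(f"{ev_path}: row {i}: {e}") from e
        lfp_meta = json.loads((pdir / "lfp.json").read_text())
        lfps: Dict[int, AnalogTrace] = {}
        for delay_class in ("short", "long"):
            lpath = pdir / f"lfp_{delay_class}.csv"
            if not lpath.exists():
                continue
            arr = np.loadtxt(lpath, delimiter=",", skiprows=1, ndmin=2)
            for row in arr:
                lfps[int(row[0])] = AnalogTrace(row[1:], fs=lfp_meta["fs"],
                                                t0=lfp_meta.get("t0", 0.0))
        sp_path = pdir / "spikes.csv"
        sp_df = pd.read_csv(sp_path)
        _require_cols(sp_df, ["trial_id", "spike_time_ms"], sp_path)
        spikes: Dict[int, SpikeTrain] = {}
        for ev in events:
            times = np.sort(sp_df.loc[sp_df.trial_id == ev.trial_id,
                                      "spike_time_ms"].to_numpy(dtype=float))
            spikes[ev.trial_id] = SpikeTrain(ev.trial_id, times)
            if ev.trial_id not in lfps:
                raise ValueError(f"{pdir}: trial {ev.trial_id} has no LFP trace")
        gt = json.loads((pdir / "ground_truth.json").read_text()) \
            if (pdir / "ground_truth.json").exists() else {}
        pairs.append(SessionPair(pair_id, events, lfps, spikes, gt))
    if not pairs:
        raise ValueError(f"{in_dir}: no pair_* directories found")
    return Session(pairs, timing, meta=meta.get("meta", {}))
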