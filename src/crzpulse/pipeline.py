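"""End-to-end pipeline orchestration.

Runs the enabled stages in dependency order on synthetic or user data,
writes every artifact as CSV/JSON under the configured output directory,
and records a manifest (config hash, per-artifact checksums, wall clock,
warnings) so identical config+seed reruns can be verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect as det
from . import shape as shp
from . import stats as st
from . import synthetic as syn
from . import tdm as tdmmod
from . import trajectory as trj
from .config import RunConfig, stage_seed

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages_run: list[str]
    checksums: dict[str, str] = field(default_factory=dict)
    wall_clock_sec: float = 0.0
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages; returns the manifest (also written).

    Missing upstream artifacts raise a dependency error naming the stage.
    """
    from . import __version__

    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.model_dump(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        version=__version__,
        stages_run=[],
    )
    th = config.thresholds.to_spec()
    caught: list[str] = []

    def record(path: Path):
        manifest.checksums[path.name] = _sha256(path)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        if "generate" in config.stages:
            seed = stage_seed(config.seed, "generate")
            gen = config.generator
            trajs, truth = [], {"bursts": {}, "pulses": {}}
            for i in range(gen.n_cells):
                cid = f"cell{i:03d}"
                ca_spec = syn.SynthCalciumSpec(
                    duration_sec=gen.duration_sec, seed=seed + 2 * i, **gen.calcium
                )
                ca, bursts = syn.gen_calcium(ca_spec)
                ca = dataclasses.replace(ca, cell_id=cid)
                crz_spec = syn.SynthCrzSpec(seed=seed + 2 * i + 1, **gen.crz1)
                crz, pulses = syn.gen_crz_train(bursts, crz_spec, gen.duration_sec, cell_id=cid)
                trajs.extend([ca, crz])
                truth["bursts"][cid] = [dataclasses.asdict(b) for b in bursts]
                truth["pulses"][cid] = [dataclasses.asdict(p) for p in pulses]
            traj_path = out / "trajectories.csv"
            trj.write_csv(trajs, traj_path)
            _write_json(truth, out / "ground_truth.json")
            record(traj_path)
            record(out / "ground_truth.json")
            manifest.stages_run.append("generate")

        def load_trajs() -> list[trj.Trajectory]:
            path = out / "trajectories.csv"
            if not path.exists():
                if config.trajectories_csv:
                    path = Path(config.trajectories_csv)
                else:
                    raise FileNotFoundError(
                        "stage 'detect' needs trajectories: run 'generate' or set trajectories_csv"
                    )
            return trj.read_csv(path)

        if "detect" in config.stages:
            trajs = load_trajs()
            if config.control_csv:
                th_local = det.compute_thresholds(trj.read_csv(config.control_csv), th)
            else:
                th_local = th
            rows = []
            for t in trajs:
                events = det.detect(t, th_local)
                for e in events:
                    rows.append(
                        {
                            "cell_id": e.cell_id,
                            "channel": t.channel,
                            "time_sec": e.time_sec,
                            "height": e.height,
                            "prominence": e.prominence,
                            "overshoot_depth": getattr(e, "overshoot_depth", np.nan),
                            "following_interval_sec": getattr(e, "following_interval_sec", np.nan),
                        }
                    )
            ev_path = out / "events.csv"
            pd.DataFrame(
                rows,
                columns=[
                    "cell_id", "channel", "time_sec", "height", "prominence",
                    "overshoot_depth", "following_interval_sec",
                ],
            ).to_csv(ev_path, index=False)
            _write_json(dataclasses.asdict(th_local), out / "thresholds.json")
            record(ev_path)
            record(out / "thresholds.json")
            manifest.stages_run.append("detect")

        def load_events():
            path = out / "events.csv"
            if not path.exists():
                raise FileNotFoundError("stage needs events.csv: run 'detect' first")
            df = pd.read_csv(path)
            bursts = [
                det.Burst(r.cell_id, r.time_sec, r.height, r.prominence,
                          r.overshoot_depth, r.following_interval_sec)
                for r in df[df.channel == "calcium"].itertuples()
            ]
            pulses = [
                det.Pulse(r.cell_id, "crz1", r.time_sec, r.height, r.prominence)
                for r in df[df.channel == "crz1"].itertuples()
            ]
            return bursts, pulses

        if "analyze" in config.stages:
            trajs = load_trajs()
            bursts, pulses = load_events()
            spans = {
                t.cell_id: (float(t.times[0]), float(t.times[-1]))
                for t in trajs
                if t.channel == "calcium"
            }
            pairings = st.pair_events(bursts, pulses, spans)
            results: dict = {}
            if len(spans) >= 2 and bursts:
                ctrl = st.randomized_control(
                    bursts, pulses, spans, seed=stage_seed(config.seed, "analyze")
                )
                m1 = [p.offsets_after[0] for p in pairings if p.offsets_after]
                c1 = [p.offsets_after[0] for p in ctrl if p.offsets_after]
                if len(m1) >= 3 and len(c1) >= 3:
                    results["first_offset_comparison"] = dataclasses.asdict(
                        st.compare_offsets(m1, c1)
                    )
            records = st.count_and_filter(pairings, config.min_interval_sec)
            if len(records) >= 3:
                try:
                    results["glm_after"] = dataclasses.asdict(
                        st.glm_count_on_height(records, "after")
                    )
                    results["glm_before"] = dataclasses.asdict(
                        st.glm_count_on_height(records, "before")
                    )
                except (RuntimeError, ValueError) as exc:
                    caught.append(f"analyze GLM: {exc}")
                if len(records) >= 4:
                    try:
                        results["residual_control"] = st.residual_control(records)
                    except ValueError as exc:
                        caught.append(f"residual control: {exc}")
                heights = sorted(r.burst_height for r in records)
                if len(set(heights)) >= 3:
                    e1 = heights[len(heights) // 3]
                    e2 = heights[2 * len(heights) // 3]
                    if e2 > e1:
                        results["height_groups"] = st.height_groups(records, [e1, e2])
            overshoot_ok = [b for b in bursts if b.height > 0]
            if len(overshoot_ok) >= 3:
                try:
                    slope, intercept, r2 = det.overshoot_regression(overshoot_ok)
                    results["overshoot_regression"] = {
                        "slope": slope, "intercept": intercept, "r_squared": r2
                    }
                except ValueError as exc:
                    caught.append(f"overshoot regression: {exc}")
            stats_path = out / "stats.json"
            _write_json(results, stats_path)
            record(stats_path)
            manifest.stages_run.append("analyze")

        if "simulate_tdm" in config.stages:
            trajs = [t for t in load_trajs() if t.channel == "calcium"]
            params = config.tdm.to_params(seed=stage_seed(config.seed, "simulate_tdm"))
            sims = []
            for t in trajs:
                p = dataclasses.replace(
                    params,
                    seed=(params.seed + tdmmod.stable_cell_hash(t.cell_id)) % (2**31),
                )
                res = tdmmod.simulate_tdm(t, p)
                sims.append(res.trajectory)
            sim_path = out / "tdm_simulated.csv"
            trj.write_csv(sims, sim_path)
            try:
                records, fit = tdmmod.predict_from_calcium(
                    trajs, params, th, min_interval_sec=config.min_interval_sec
                )
                _write_json(
                    {"records": records, "glm": dataclasses.asdict(fit)},
                    out / "tdm_prediction.json",
                )
                record(out / "tdm_prediction.json")
            except RuntimeError as exc:
                caught.append(f"simulate_tdm prediction: {exc}")
            record(sim_path)
            manifest.stages_run.append("simulate_tdm")

        if "simulate_csm" in config.stages:
            csm_traj = tdmmod.simulate_csm(config.csm.to_params())
            csm_path = out / "csm_simulated.csv"
            trj.write_csv([csm_traj], csm_path)
            record(csm_path)
            manifest.stages_run.append("simulate_csm")

        if "fit_pulses" in config.stages:
            seed = stage_seed(config.seed, "fit_pulses")
            rows = []
            for model in ("tdm", "csm"):
                fits = tdmmod.two_pulse_shape_fits(
                    model=model, n_cells=30, seed=seed,
                    tdm_params=config.tdm.to_params(seed=seed),
                    csm_params=config.csm.to_params(),
                )
                for f in fits:
                    for ordinal, p in enumerate(f.pulses, start=1):
                        rows.append(
                            {
                                "model": model, "ordinal": ordinal,
                                "h": p.h, "r": p.r, "a": p.a, "b": p.b,
                                "r_squared": f.r_squared,
                            }
                        )
            fit_path = out / "pulse_fits.csv"
            pd.DataFrame(rows).to_csv(fit_path, index=False)
            record(fit_path)
            manifest.stages_run.append("fit_pulses")

        if "periodicity" in config.stages:
            trajs = load_trajs()
            bursts, _ = load_events() if (out / "events.csv").exists() else ([], [])
            rows = []
            by_cell_b: dict[str, list] = {}
            for b in bursts:
                by_cell_b.setdefault(b.cell_id, []).append(b)
            for t in trajs:
                if t.channel != "crz1":
                    continue
                seg = shp.post_burst_segment(t, by_cell_b.get(t.cell_id, []))
                if seg is None:
                    continue
                try:
                    res = shp.gp_llr(seg)
                except Exception as exc:  # noqa: BLE001 - record and continue
                    caught.append(f"periodicity {t.cell_id}: {exc}")
                    continue
                biggest = max(by_cell_b[t.cell_id], key=lambda b: b.height)
                rows.append(
                    {
                        "cell_id": t.cell_id,
                        "burst_height": biggest.height,
                        "llr": res.llr,
                        "period": res.periodic_params["period"],
                    }
                )
            llr_path = out / "periodicity.csv"
            pd.DataFrame(rows, columns=["cell_id", "burst_height", "llr", "period"]).to_csv(
                llr_path, index=False
            )
            record(llr_path)
            manifest.stages_run.append("periodicity")

        caught.extend(str(w.message) for w in wlist)

    manifest.warnings = caught
    manifest.wall_clock_sec = time.time() - t_start
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
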