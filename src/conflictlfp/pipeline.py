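"""End-to-end orchestration: simulate -> preprocess -> behavior -> select
-> trial stats -> group stats -> latency -> cross-frequency coupling.

A :class:`RunConfig` (YAML-serialisable) fixes every stage's parameters
and seeds; outputs are TSV/JSON files under the run directory, each
stamped with the config hash so a bundle is self-describing.  Re-running
with an identical config reproduces the outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, cfc, group_stats, latency, selectivity, trial_stats
from .preprocess import epoch_band_power, notch_and_rereference, \
    subset_channels
from .synth import SimConfig, make_channel_plan, simulate_subject

log = logging.getLogger("conflictlfp")

STAGES = ("simulate", "behavior", "select", "trialstats", "groupstats",
          "latency", "cfc")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    band: str = "high-gamma"
    alpha: float = 0.001
    min_run_ms: float = 50.0
    n_perm_threshold: int = 1000
    n_boot_latency: int = 200
    n_perm_latency: int = 2000
    n_perm_trialstats: int = 1000
    n_surr_cfc: int = 200
    stim_window: tuple = (-0.5, 1.5)
    resp_window: tuple = (-1.5, 0.5)
    seed: int = 0
    stages: tuple = STAGES
    sim: SimConfig = field(default_factory=SimConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise PipelineError("config", f"unknown keys: {sorted(bad)}")
        cfg = cls(sim=sim, **raw)
        return cfg

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # paths do not define the computation
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(cfg: RunConfig) -> dict:
    from . import __version__
    return {"config_hash": cfg.config_hash(), "version": __version__}


def _write_tsv(path: Path, df: pd.DataFrame, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        st = _stamp(cfg)
        fh.write(f"# config_hash={st['config_hash']} "
                 f"version={st['version']}\n")
        df.to_csv(fh, sep="\t", index=False)


def _write_json(path: Path, obj: dict, cfg: RunConfig) -> None:
    from .io import write_json
    obj = {**obj, "_provenance": _stamp(cfg)}
    write_json(path, obj)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages on a synthetic cohort; returns the
    report bundle (also written under ``cfg.out_dir``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    plan = make_channel_plan(sim)
    analysed = plan[~plan["aux"]]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))

    # ---- simulate + preprocess --------------------------------------
    if "simulate" not in cfg.stages:
        raise PipelineError("simulate", "pipeline currently runs on the "
                            "synthetic cohort; enable the simulate stage")
    subj_trials, tens_stim, tens_resp, labels = {}, {}, {}, {}
    try:
        for s in range(sim.n_subjects):
            trials, rec = simulate_subject(sim, s, plan=plan)
            rec = notch_and_rereference(rec)
            rec = subset_channels(rec, ~rec.channels["aux"].to_numpy(bool))
            ok = trials["correct"] & trials["rt"].notna()
            tri = trials[ok].reset_index(drop=True)
            ts = epoch_band_power(rec, tri, cfg.band, "stimulus",
                                  cfg.stim_window)
            tr_ = epoch_band_power(rec, tri, cfg.band, "response",
                                   cfg.resp_window)
            subj_trials[s] = (trials, tri)
            tens_stim[s], tens_resp[s] = ts, tr_
            lab = (tri["congruency"] == "I").to_numpy()
            labels[s] = (lab[ts.trial_index], lab[tr_.trial_index])
            log.info("subject %d: %d trials (%d dropped stim, %d resp)",
                     s, len(tri), ts.n_dropped, tr_.n_dropped)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", str(e)) from e

    # ---- behavior ----------------------------------------------------
    if "behavior" in cfg.stages:
        try:
            allt = pd.concat([t.assign(subject=s)
                              for s, (t, _) in subj_trials.items()])
            summ = behavior.behavioral_summary(allt)
            bundle["behavior"] = {
                k: v for k, v in summ.items()
                if not isinstance(v, pd.DataFrame)}
            _write_json(out / "behavior.json", bundle["behavior"], cfg)
            _write_tsv(out / "behavior_per_subject.tsv",
                       summ["per_subject"], cfg)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("behavior", str(e)) from e

    # ---- selectivity -------------------------------------------------
    sel_rows = []
    if "select" in cfg.stages:
        try:
            for s in range(sim.n_subjects):
                chans = analysed[analysed["subject"] == s].reset_index(drop=True)
                for e in range(len(chans)):
                    res = selectivity.select_electrode(
                        tens_resp[s], labels[s][1], e, cfg.alpha,
                        cfg.n_perm_threshold, rng, cfg.min_run_ms)
                    row = dict(subject=s,
                               electrode=int(chans.loc[e, "channel"]),
                               region=chans.loc[e, "region"],
                               alignment="response",
                               selective=res.selective,
                               amplitude_ok=res.amplitude_ok,
                               latency=res.latency,
                               pre_response=res.pre_response)
                    if res.selective and res.pre_response:
                        thr = res.threshold
                        mean, sem, lost = selectivity.latency_bootstrap(
                            tens_resp[s], labels[s][1], thr, e,
                            cfg.n_boot_latency, rng, cfg.min_run_ms)
                        row.update(latency_mean=mean, latency_sem=sem,
                                   boot_lost=lost)
                    sel_rows.append(row)
            sel_df = pd.DataFrame(sel_rows)
            bundle["selectivity"] = sel_df
            _write_tsv(out / "selectivity.tsv", sel_df, cfg)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("select", str(e)) from e

    # ---- single-electrode statistics --------------------------------
    if "trialstats" in cfg.stages:
        try:
            rows = []
            sel_df = bundle.get("selectivity")
            picks = sel_df[sel_df["selective"]] if sel_df is not None \
                else pd.DataFrame()
            for _, prow in picks.iterrows():
                s = int(prow["subject"])
                chans = analysed[analysed["subject"] == s].reset_index(drop=True)
                e = int(chans.index[chans["channel"] ==
                                    prow["electrode"]][0])
                tri = subj_trials[s][1]
                tt = tens_resp[s]
                sc = trial_stats.single_trial_power(tt, e, "max")
                lab = labels[s][1]
                rts = tri["rt"].to_numpy()[tt.trial_index]
                r, p = trial_stats.power_rt_correlation(
                    sc.values[lab], rts[lab], cfg.n_perm_trialstats, rng)
                hist = tri["history"].to_numpy()[tt.trial_index]
                rep = tri["stim_repeat"].to_numpy()[tt.trial_index]
                keep = ~rep
                try:
                    anc, anc_p = trial_stats.gratton_ancova(
                        sc.values[keep], hist[keep], rts[keep])
                except trial_stats.TrialStatsError:
                    anc, anc_p = np.nan, np.nan
                rows.append(dict(subject=s, electrode=prow["electrode"],
                                 region=prow["region"], power_rt_r=r,
                                 power_rt_p=p, gratton_ancova=anc,
                                 gratton_ancova_p=anc_p))
            ts_df = pd.DataFrame(rows)
            bundle["trial_stats"] = ts_df
            if len(ts_df):
                _write_tsv(out / "trial_stats.tsv", ts_df, cfg)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("trialstats", str(e)) from e

    # ---- group statistics -------------------------------------------
    if "groupstats" in cfg.stages:
        try:
            sel_df = bundle.get("selectivity")
            recs = []
            picks = sel_df[sel_df["selective"]] if sel_df is not None \
                else pd.DataFrame()
            for _, prow in picks.iterrows():
                s = int(prow["subject"])
                chans = analysed[analysed["subject"] == s].reset_index(drop=True)
                e = int(chans.index[chans["channel"] ==
                                    prow["electrode"]][0])
                tt = tens_resp[s]
                sc = trial_stats.single_trial_power(tt, e, "max")
                tri = subj_trials[s][1]
                cong = tri["congruency"].to_numpy()[tt.trial_index]
                recs.append(pd.DataFrame(dict(
                    power=sc.values, congruency=cong, subject=s,
                    electrode=prow["electrode"])))
            if recs and len({r["subject"].iloc[0] for r in recs}) < 2:
                log.warning("groupstats skipped: selective electrodes "
                            "from a single subject")
                recs = []
            if recs:
                dat = pd.concat(recs, ignore_index=True)
                res = group_stats.multilevel_test(
                    dat, "power", "congruency", "1",
                    tested_term="congruency")
                bundle["group_congruency"] = dataclasses.asdict(res) | {
                    "fitted_means": None}
                _write_json(out / "group_congruency.json",
                            bundle["group_congruency"], cfg)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("groupstats", str(e)) from e

    # ---- latency hierarchy ------------------------------------------
    if "latency" in cfg.stages:
        try:
            sel_df = bundle.get("selectivity")
            qual = sel_df[(sel_df["selective"]) &
                          (sel_df["pre_response"] == True)]  # noqa: E712
            qual = qual.rename(columns={"latency": "latency"})
            if len(qual) >= 4:
                lat = latency.region_latency_test(
                    qual[["electrode", "subject", "region", "latency"]],
                    cfg.n_perm_latency, rng)
                bundle["latency"] = lat
                _write_tsv(out / "latency_pairs.tsv", lat["pairs"], cfg)
                _write_json(out / "latency_test.json",
                            {"F": lat["F"], "p": lat["p"],
                             "table": lat["table"]}, cfg)
            else:
                log.warning("latency stage skipped: <4 qualifying "
                            "electrodes")
        except latency.LatencyError as e:
            log.warning("latency stage: %s", e)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("latency", str(e)) from e

    # ---- cross-frequency coupling -----------------------------------
    if "cfc" in cfg.stages:
        try:
            s = 0
            trials, rec = simulate_subject(sim, s, plan=plan)
            rec = notch_and_rereference(rec)
            rec = subset_channels(rec, ~rec.channels["aux"].to_numpy(bool))
            x = rec.signal[0]
            phase, amp = cfc.phase_amplitude(x, rec.fs)
            pac = cfc.mi_surrogate_test(phase, amp, rec.fs,
                                        max(cfg.n_surr_cfc, 100), rng)
            bundle["cfc"] = {"mi": pac.mi, "p": pac.p}
            _write_json(out / "cfc.json", bundle["cfc"], cfg)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("cfc", str(e)) from e

    _write_json(out / "run_summary.json",
                {"stages": list(cfg.stages),
                 "n_selective": int(bundle["selectivity"]["selective"].sum())
                 if "selectivity" in bundle else None}, cfg)
    return bundle
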