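"""End-to-end orchestration: simulate/load -> exposure -> stats -> SVR.

The pipeline mirrors the analysis order of a season-long head-impact study:
hit-log summaries, cohort force thresholds, suprathreshold and exclusive
counts, decile dose-response sweep, paired pre/post FA tests, the
fingerprint -> laterality SVR with its permutation null and relevance map,
and the tau-FA association. Every run writes a manifest (seed, config echo
and hash, package version) next to its tables so results are auditable and
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, SyntheticCohort, simulate_cohort
from .hits import (FingerprintBinner, cohort_thresholds, count_exclusive,
                   decile_thresholds, read_hit_log, summarize_hit_log,
                   suprathreshold_counts_by_player)
from .stats import (dose_response_sweep, paired_location_test, tau_fa_association)
from .svr import LateralitySVR, bonferroni_alpha

log = logging.getLogger("headimpact")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (mirrors the CLI flags)."""

    out_dir: str = "headimpact_out"
    hits_csv: str | None = None          # None -> simulate
    outcomes_csv: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    threshold_mode: str = "cohort-sd"    # cohort-sd | explicit | decile-sweep
    explicit_linear: float | None = None
    explicit_rotational: float | None = None
    svr_nu: float = 20.0 / 37.0
    svr_C: float = 10.0
    n_permutations: int = 1000
    run_svr: bool = True
    run_roi: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns {stage: output path or object}.

    Any stage failure raises with the stage name prepended, so a broken
    input is attributable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    t0 = time.time()
    try:
        stage = "load-or-simulate"
        if config.hits_csv is None:
            cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
            cohort = simulate_cohort(cohort_cfg)
            cohort.write(out / "synthetic")
            hits, outcomes = cohort.hits, cohort.outcomes
            results["synthetic"] = str(out / "synthetic")
        else:
            hits = read_hit_log(config.hits_csv)
            outcomes = pd.read_csv(config.outcomes_csv) if config.outcomes_csv else None
        log.info("stage %s done (%.2fs)", stage, time.time() - t0)

        stage = "summarize"
        summary = summarize_hit_log(hits)
        summary.to_csv(out / "hit_summary.csv")
        results["summary"] = summary

        stage = "thresholds"
        if config.threshold_mode == "explicit":
            if config.explicit_linear is None or config.explicit_rotational is None:
                raise ValueError("explicit threshold mode needs both thresholds")
            lin_thr, rot_thr = config.explicit_linear, config.explicit_rotational
            provenance = "user-supplied"
        else:
            ts = cohort_thresholds(hits)
            lin_thr, rot_thr = ts.linear_threshold, ts.rotational_threshold
            provenance = ts.provenance
        pd.DataFrame([{"linear_threshold_g": lin_thr,
                       "rotational_threshold_rad_s2": rot_thr,
                       "provenance": provenance}]).to_csv(
            out / "thresholds.csv", index=False)
        results["thresholds"] = (lin_thr, rot_thr)

        stage = "counts"
        players = (outcomes["player_id"].tolist() if outcomes is not None
                   else sorted(pd.unique(hits["player_id"])))
        counts = pd.DataFrame({
            "player_id": players,
            "n_supra_rotational": suprathreshold_counts_by_player(
                hits, "rotational", rot_thr, players),
            "n_supra_linear": suprathreshold_counts_by_player(
                hits, "linear", lin_thr, players),
        }).set_index("player_id")
        counts["n_rot_only"] = [
            count_exclusive(hits[hits.player_id == p], rot_thr, lin_thr, "rot_only")
            for p in players]
        counts["n_lin_only"] = [
            count_exclusive(hits[hits.player_id == p], rot_thr, lin_thr, "lin_only")
            for p in players]
        counts.to_csv(out / "suprathreshold_counts.csv")
        results["counts"] = counts

        stage = "fingerprints"
        binner = FingerprintBinner(roster=players).fit(hits)
        F = binner.transform(hits)
        pd.DataFrame(F, index=pd.Index(binner.players_, name="player_id")).to_csv(
            out / "fingerprints.csv")
        results["fingerprints"] = F

        if outcomes is not None:
            stage = "paired-tests"
            rows = []
            for hemi in ("left", "right"):
                t_res, w_res = paired_location_test(outcomes[f"fa_pre_{hemi}"],
                                                    outcomes[f"fa_post_{hemi}"])
                for r in (t_res, w_res):
                    rows.append({"hemisphere": hemi, **r.to_dict()})
            pd.DataFrame(rows).to_csv(out / "paired_tests.csv", index=False)
            results["paired_tests"] = pd.DataFrame(rows)

            stage = "dose-response"
            thresholds = (decile_thresholds(hits, "rotational")
                          if config.threshold_mode == "decile-sweep"
                          else [rot_thr])
            sweep = dose_response_sweep(hits, "rotational", outcomes, thresholds)
            sweep.to_csv(out / "dose_response.csv", index=False)
            results["dose_response"] = sweep

            if config.run_svr:
                stage = "svr"
                y = outcomes.set_index("player_id")["laterality"].loc[
                    binner.players_].to_numpy()
                est = LateralitySVR(nu=config.svr_nu, C=config.svr_C).fit(F, y)
                perm = est.permutation_test(config.n_permutations,
                                            random_state=config.seed)
                pd.DataFrame({
                    "player_id": binner.players_, "observed": y,
                    "predicted": est.oof_prediction_,
                }).to_csv(out / "svr_predictions.csv", index=False)
                grid = est.relevance_.reshape(36, 18)
                pd.DataFrame(grid).to_csv(out / "svr_relevance_grid.csv", index=False)
                svr_json = {
                    "r_squared": est.r_squared_,
                    "permutation_p": perm.pvalue,
                    "n_permutations": perm.n_permutations,
                    "nu": config.svr_nu, "C": config.svr_C,
                    "sv_counts": est.sv_counts_.tolist(),
                    "n_significant_bins": int(est.significant_bins_.sum()),
                    "bonferroni_alpha": bonferroni_alpha(0.05, est.relevance_.size),
                    "null_r2_mean": float(np.mean(perm.null_r2)),
                    "null_r2_q99": float(np.quantile(perm.null_r2, 0.99)),
                }
                (out / "svr_result.json").write_text(json.dumps(svr_json, indent=2))
                results["svr"] = svr_json

            if "tau" in outcomes and outcomes["tau"].notna().sum() >= 4:
                stage = "tau"
                sub = outcomes[outcomes["tau"].notna()]
                res = tau_fa_association(sub["tau"], sub["fa_post_right"])
                pd.DataFrame([res.to_dict()]).to_csv(out / "tau_association.csv",
                                                     index=False)
                results["tau"] = res

        stage = "manifest"
        manifest = {
            "package": "headimpact", "version": __version__,
            "seed": config.seed, "config_hash": config.config_hash(),
            "config": _jsonable(dataclasses.asdict(config)),
            "stages": sorted(results),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        results["manifest"] = manifest
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
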