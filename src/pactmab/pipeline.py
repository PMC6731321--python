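"""End-to-end orchestration: generate/load -> calibrate -> verify -> synergy.

The pipeline reproduces the analysis workflow on a synthetic (or user
supplied) panel: control fits define (k, theta) ranges; each monotherapy
dataset gets a pre-treatment fit plus a multistart drug-parameter fit; a
parameter-recovery study quantifies calibration error (and supplies the
combination "tuning" intervals); each combination regimen is calibrated for
the synergy multiplier S; finally the Loewe combination index is computed
from the panel's own day-4 dose-response tables.

All randomness flows from one root seed through named per-stage substreams,
so every stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, Optional

from .calibration import (
    DRUG_PARAMS,
    RecoveryReport,
    fit_combination,
    fit_controls,
    fit_pretreatment,
    fit_single_drug,
    run_verification_study,
)
from .dataset import ConfluenceDataset, read_confluence_csv, write_confluence_csv
from .generate import NoiseModel, generate_panel, panel_conditions
from .synergy import DoseResponseTable, combination_index

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "full_pipeline"]


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 0
    out_dir: Optional[str] = None
    data_csv: Optional[str] = None  # load instead of generate
    noise_scale: float = 0.025
    noise_kind: str = "additive-gaussian"
    n_replicates: int = 8
    n_starts: int = 20
    verification_sets: int = 4
    verification_starts: int = 10
    run_verification: bool = True
    run_combinations: bool = True
    run_synergy: bool = True
    s_max: float = 5.0
    unit_mode: str = "normalized"

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def full_pipeline(config: RunConfig) -> Dict:
    """Run the complete analysis and return (and optionally write) a report.

    The report bundle contains per-condition calibration results, the
    recovery report, the fitted synergy multipliers and the combination
    indices, all keyed the way the study's summary tables are laid out.
    """
    t_start = time.time()
    noise = NoiseModel(
        kind=config.noise_kind,
        scale=config.noise_scale,
        n_replicates=config.n_replicates,
    )
    report: Dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    regimens = panel_conditions()

    # ------------------------------------------------------------------ data
    stage_t = time.time()
    if config.data_csv:
        loaded = read_confluence_csv(config.data_csv)
        if isinstance(loaded, ConfluenceDataset):
            loaded = {loaded.condition: loaded}
        panel = {
            name: (ds, None, regimens[name])
            for name, ds in loaded.items()
            if name in regimens
        }
        unknown = set(loaded) - set(regimens)
        if unknown:
            logger.warning("ignoring conditions with no known regimen: %s", sorted(unknown))
    else:
        panel = generate_panel(seed=_stage_seed(config.seed, "generate"), noise=noise)
    report["stages"]["data"] = {
        "n_conditions": len(panel),
        "source": config.data_csv or "generated",
        "wall_time_s": round(time.time() - stage_t, 2),
    }

    # -------------------------------------------------------------- controls
    stage_t = time.time()
    controls = [ds for name, (ds, _t, _r) in panel.items() if not _r.events]
    control_bounds = fit_controls(
        controls, seed=_stage_seed(config.seed, "controls"), n_starts=config.n_starts
    )
    report["stages"]["controls"] = {
        "bounds": {k: list(v) for k, v in control_bounds.bounds.items()},
        "provenance": control_bounds.provenance,
        "wall_time_s": round(time.time() - stage_t, 2),
    }

    # ---------------------------------------------------------- monotherapies
    stage_t = time.time()
    mono_results: Dict[str, Dict] = {}
    single_fits: Dict[str, Dict] = {}
    for name, (ds, truth, reg) in panel.items():
        if len({e.drug for e in reg.events}) != 1:
            continue
        drug = reg.events[0].drug
        pre = fit_pretreatment(
            ds, control_bounds, n_starts=config.n_starts,
            seed=_stage_seed(config.seed, f"pre:{name}"),
        )
        res = fit_single_drug(
            ds, reg, drug, pre.params.k, pre.params.theta,
            n_starts=config.n_starts, seed=_stage_seed(config.seed, f"drug:{name}"),
        )
        single_fits[name] = {
            "drug": drug,
            "dose": reg.events[0].dose,
            "k": pre.params.k,
            "theta": pre.params.theta,
            "values": res.fitted_values(),
            "day4_model": None,
        }
        entry = {
            "drug": drug,
            "dose": reg.events[0].dose,
            "k": pre.params.k,
            "theta": pre.params.theta,
            **res.fitted_values(),
            "l2_err": res.objective,
            "ccc": res.ccc,
        }
        if truth is not None:
            entry["truth"] = truth.to_dict()
        mono_results[name] = entry
    report["stages"]["monotherapies"] = {
        "results": mono_results,
        "wall_time_s": round(time.time() - stage_t, 2),
    }

    # ------------------------------------------------------------ verification
    recovery: Optional[RecoveryReport] = None
    if config.run_verification:
        stage_t = time.time()
        recovery = run_verification_study(
            n_sets=config.verification_sets,
            n_starts=config.verification_starts,
            noise=noise,
            seed=_stage_seed(config.seed, "verification"),
        )
        report["stages"]["verification"] = {
            "per_parameter": {
                k: {"mean_abs_pct_error": v[0], "n": v[1]}
                for k, v in recovery.per_parameter.items()
            },
            "median_pct": recovery.median_error_pct,
            "max_pct": recovery.max_error_pct,
            "min_pct": recovery.min_error_pct,
            "n_failed": recovery.n_failed,
            "wall_time_s": round(time.time() - stage_t, 2),
        }

    # ------------------------------------------------------------ combinations
    if config.run_combinations:
        if recovery is None:
            # tuning intervals need recovery errors; a pipeline configured
            # without the verification stage uses a nominal 5% interval
            recovery = RecoveryReport.from_errors(
                {p: 5.0 for names in DRUG_PARAMS.values() for p in names}
            )
        stage_t = time.time()
        combo_results: Dict[str, Dict] = {}
        for name, (ds, truth, reg) in panel.items():
            if len({e.drug for e in reg.events}) != 2:
                continue
            pac_dose = next(e.dose for e in reg.events if e.drug == "paclitaxel")
            mono_pac = next(
                (v for v in single_fits.values()
                 if v["drug"] == "paclitaxel" and v["dose"] == pac_dose), None
            )
            tmab_dose = next(e.dose for e in reg.events if e.drug == "trastuzumab")
            mono_tmab = next(
                (v for v in single_fits.values()
                 if v["drug"] == "trastuzumab" and v["dose"] == tmab_dose), None
            )
            if mono_pac is None or mono_tmab is None:
                logger.warning("skipping %s: missing monotherapy fit", name)
                continue
            pre = fit_pretreatment(
                ds, control_bounds, n_starts=config.n_starts,
                seed=_stage_seed(config.seed, f"pre:{name}"),
            )
            res = fit_combination(
                ds, reg,
                pac_values=mono_pac["values"],
                tmab_values=mono_tmab["values"],
                recovery_report=recovery,
                k=pre.params.k, theta=pre.params.theta,
                n_starts=config.n_starts,
                seed=_stage_seed(config.seed, f"combo:{name}"),
                s_max=config.s_max,
            )
            entry = {
                "regimen": reg.name,
                "pac_dose": pac_dose,
                "tmab_dose": tmab_dose,
                "S": res.params.S,
                "l2_err": res.objective,
                "ccc": res.ccc,
            }
            if truth is not None:
                entry["S_truth"] = truth.S
            combo_results[name] = entry
        report["stages"]["combinations"] = {
            "results": combo_results,
            "wall_time_s": round(time.time() - stage_t, 2),
        }

    # ---------------------------------------------------------------- synergy
    if config.run_synergy:
        stage_t = time.time()
        tables: Dict[str, DoseResponseTable] = {}
        for drug in ("paclitaxel", "trastuzumab"):
            entries = sorted(
                (
                    (v["dose"], panel[n][0].mean[-1])
                    for n, v in single_fits.items()
                    if v["drug"] == drug
                ),
            )
            if len(entries) >= 2:
                tables[drug] = DoseResponseTable(
                    drug=drug,
                    doses=[e[0] for e in entries],
                    responses=[e[1] for e in entries],
                )
        ci_results: Dict[str, Dict] = {}
        if len(tables) == 2:
            for name, (ds, _t, reg) in panel.items():
                if len({e.drug for e in reg.events}) != 2:
                    continue
                pac_dose = next(e.dose for e in reg.events if e.drug == "paclitaxel")
                tmab_dose = next(e.dose for e in reg.events if e.drug == "trastuzumab")
                res = combination_index(
                    pac_dose, tmab_dose, float(ds.mean[-1]),
                    tables["paclitaxel"], tables["trastuzumab"],
                )
                ci_results[name] = {
                    "kind": res.kind,
                    "value": res.value,
                    "interval": list(res.interval) if res.interval else None,
                    "classification": res.classification,
                }
        report["stages"]["synergy"] = {
            "results": ci_results,
            "wall_time_s": round(time.time() - stage_t, 2),
        }

    report["wall_time_s"] = round(time.time() - t_start, 2)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        if not config.data_csv:
            write_confluence_csv([ds for ds, _t, _r in panel.values()], out / "panel.csv")
            truths = {
                n: t.to_dict() for n, (_d, t, _r) in panel.items() if t is not None
            }
            with open(out / "truth_params.json", "w") as fh:
                json.dump({"config_hash": report["config_hash"], "seed": config.seed,
                           "truth": truths}, fh, indent=2)
        if recovery is not None and config.run_verification:
            recovery.to_frame().to_csv(out / "recovery_report.csv", index=False)
    return report
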