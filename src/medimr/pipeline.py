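"""Orchestration of the full mediation study on synthetic or user-supplied data.

Workflow per candidate mediator: instrument selection, harmonization, the
six-method univariable MR panel with the full sensitivity suite, outlier
removal and re-estimation, the sequential mediator screen, MVMR direct
effects, and the mediation decomposition with both second-step variants,
ending in a ranked proportion table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import mediation, mvmr, sensitivity, sumstats, synthgwas, uvmr

ALPHA = 0.05           # two-sided significance gate used throughout
COND_F_MIN = 10.0      # weak-instrument bound
MAX_OUTLIER_ROUNDS = 2  # detect -> remove -> re-estimate, at most twice


@dataclass
class ScreenDecision:
    """Outcome of the sequential mediator screen.

    Gates run in order: step 1 (exposure->mediator significant), step 2
    (mediator->outcome significant), instrument strength (conditional F >=
    10), MVMR direct-effect significance; the first failed gate fixes
    ``final_status``.
    """

    mediator: str
    step1_pass: bool = False
    step2_pass: bool = False
    weak_instrument: bool = False
    mvmr_significant: bool = False
    final_status: str = "excluded_step1"
    notes: list = field(default_factory=list)


def screen_mediator(step1: uvmr.MrEstimate | None, step2: uvmr.MrEstimate | None,
                    cond_f: float | None, mvmr_est: uvmr.MrEstimate | None,
                    alpha: float = ALPHA, mediator: str = "") -> ScreenDecision:
    """Apply the sequential screening gates to one candidate mediator."""
    d = ScreenDecision(mediator=mediator)
    if step1 is None or step1.pval >= alpha:
        d.final_status = "excluded_step1"
        return d
    d.step1_pass = True
    if step2 is None or step2.pval >= alpha:
        d.final_status = "excluded_step2"
        return d
    d.step2_pass = True
    if cond_f is not None and cond_f < COND_F_MIN:
        d.weak_instrument = True
        d.final_status = "excluded_weak"
        return d
    if mvmr_est is None or mvmr_est.pval >= alpha:
        d.final_status = "excluded_mvmr"
        return d
    d.mvmr_significant = True
    d.final_status = "mediator"
    return d


def _estimate_to_dict(est):
    if est is None:
        return None
    if isinstance(est, dict):
        return est
    return {
        "method": est.method, "beta": est.beta, "se": est.se,
        "ci_low": est.ci_low, "ci_high": est.ci_high,
        "or": est.or_value, "or_ci": list(est.or_ci),
        "p": est.pval, "n_snp": est.n_snp,
    }


def _uvmr_with_outlier_loop(h, seed, n_presso=500):
    """UVMR panel with sensitivity suite; radial/PRESSO outliers removed and
    the panel re-estimated, at most MAX_OUTLIER_ROUNDS times."""
    removed = []
    for _ in range(MAX_OUTLIER_ROUNDS):
        report = sensitivity.full_report(h, n_sim=n_presso, seed=seed)
        outliers = set(report.presso_outlier_ids) | set(report.radial_outlier_ids)
        outliers -= set(removed)
        if not outliers or h.n_snp - len(outliers) < 3:
            break
        keep = ~np.isin(h.snp_ids.astype(str), list(outliers))
        h = h.subset(keep)
        removed.extend(sorted(outliers))
    panel = uvmr.run_uvmr(h, seed=seed)
    report = sensitivity.full_report(h, n_sim=n_presso, seed=seed)
    return h, panel, report, removed


def run_mediation_study(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the full screening + mediation workflow from a config mapping/YAML.

    The config either names summary-statistics files (``exposure``,
    ``outcome``, ``mediators`` with per-trait ``path``/``column_map``) or a
    synthetic scenario block (``simulate: {mediators: [{name, theta_em,
    theta_my, ...}]}``).  Returns the report bundle as a dict and, when
    ``out_dir`` is given, writes ``report.json`` plus a ranked proportion
    table ``proportions.tsv``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", ALPHA))
    p_threshold = float(config.get("p_threshold", sumstats.DEFAULT_P_THRESHOLD))

    datasets = _load_inputs(config, seed)
    exposure, outcome = datasets["exposure"], datasets["outcome"]
    report = {"seed": seed, "alpha": alpha, "mediators": {}, "proportions": []}

    # total effect once
    exp_iv = sumstats.select_instruments(exposure, p_threshold=p_threshold)
    h_total = sumstats.harmonize([mediation._restrict(exposure, exp_iv)], outcome)
    h_total, total_panel, total_report, _ = _uvmr_with_outlier_loop(h_total, seed)
    total = total_panel["ivw"]
    report["total_effect"] = {k: _estimate_to_dict(v) for k, v in total_panel.items()}

    for name, med in datasets["mediators"].items():
        entry = {"errors": []}
        try:
            med_iv = sumstats.select_instruments(med, p_threshold=p_threshold)

            h1 = sumstats.harmonize([mediation._restrict(exposure, exp_iv)], med)
            h1, step1_panel, rep1, rm1 = _uvmr_with_outlier_loop(h1, seed)
            step1 = step1_panel["ivw"]

            h2 = sumstats.harmonize([mediation._restrict(med, med_iv)], outcome)
            h2, step2_panel, rep2, rm2 = _uvmr_with_outlier_loop(h2, seed)
            step2 = step2_panel["ivw"]

            # MVMR: mediator adjusted for exposure on the instrument union
            union = list(dict.fromkeys(
                list(med_iv.table["SNP"]) + list(exp_iv.table["SNP"])))
            h_mv = sumstats.harmonize(
                [mediation._restrict_ids(med, union),
                 mediation._restrict_ids(exposure, union)], outcome)
            mv_ests = mvmr.mvmr_ivw(h_mv)
            mv_med = mv_ests[0]
            strength = sensitivity.instrument_strength(h_mv)
            cond_f = strength["conditional_f"].get(med.trait_name)

            decision = screen_mediator(step1, step2, cond_f, mv_med,
                                       alpha=alpha, mediator=name)

            entry.update({
                "step1": _estimate_to_dict(step1),
                "step2": _estimate_to_dict(step2),
                "mvmr": _estimate_to_dict(mv_med),
                "conditional_f": cond_f,
                "outliers_removed": {"step1": rm1, "step2": rm2},
                "sensitivity_step2": asdict(rep2),
                "screen": asdict(decision),
            })

            if decision.final_status == "mediator":
                for variant, est2 in (("uvmr", step2), ("mvmr_adjusted", mv_med)):
                    res = mediation.MediationResult(
                        exposure=exposure.trait_name, mediator=name,
                        outcome=outcome.trait_name,
                        theta_total=total.beta, se_total=total.se,
                        theta_1=step1.beta, se_1=step1.se,
                        theta_2=est2.beta, se_2=est2.se,
                        step2_variant=variant,
                    )
                    entry[f"mediation_{variant}"] = {
                        "indirect": res.indirect, "se_indirect": res.se_indirect,
                        "proportion": res.proportion, "se": res.se_proportion,
                        "ci": [res.ci_low, res.ci_high],
                    }
                    if variant == "uvmr":
                        report["proportions"].append(
                            {"mediator": name, "proportion": res.proportion,
                             "se": res.se_proportion,
                             "ci": [res.ci_low, res.ci_high]})
        except (sumstats.SumstatsError, uvmr.EstimationError, ValueError) as exc:
            entry["errors"].append(str(exc))
            entry["screen"] = asdict(ScreenDecision(
                mediator=name, final_status="excluded_step1",
                notes=[f"stage failure: {exc}"]))
        report["mediators"][name] = entry

    report["proportions"].sort(key=lambda r: r["proportion"], reverse=True)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        with open(out_dir / "proportions.tsv", "w") as fh:
            fh.write("mediator\tproportion\tse\tci_low\tci_high\n")
            for row in report["proportions"]:
                fh.write(f"{row['mediator']}\t{row['proportion']:.6f}\t"
                         f"{row['se']:.6f}\t{row['ci'][0]:.6f}\t{row['ci'][1]:.6f}\n")
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _load_inputs(config: dict, seed: int) -> dict:
    """Resolve config into SummaryStats objects (files or synthetic scenarios)."""
    if "simulate" in config:
        sim = dict(config["simulate"])
        specs = sim.pop("mediators")
        exposure, outcome, mediators, _ = synthgwas.simulate_study(
            specs, seed=seed, **sim)
        return {"exposure": exposure, "outcome": outcome, "mediators": mediators}

    def _read(entry, default_name):
        return sumstats.read_sumstats(
            entry["path"], column_map=entry.get("column_map"),
            trait_name=entry.get("name", default_name),
            trait_type=entry.get("trait_type", "quantitative"))

    exposure = _read(config["exposure"], "exposure")
    outcome = _read(config["outcome"], "outcome")
    mediators = {}
    for i, entry in enumerate(config.get("mediators", [])):
        med = _read(entry, f"mediator_{i + 1}")
        mediators[med.trait_name] = med
    return {"exposure": exposure, "outcome": outcome, "mediators": mediators}
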