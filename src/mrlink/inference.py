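"""Bidirectional MR orchestration, multiple-testing thresholds, the
causal-link decision rule, and statistical power.

A causal link is declared only when (i) the surviving instrument set has at
least ``min_ivs`` instruments, (ii) the seven estimators agree in sign with
IVW, and (iii) the IVW p-value clears the configured threshold —
Bonferroni-corrected (alpha / n_phenotypes / n_directions) for significance,
or the nominal threshold for suggestive evidence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import (CausalEstimate, EstimatorConfig, all_estimates, ivw_mre)
from .gwas_io import ConfounderSnpList, GwasSummaryTable, LdReference
from .harmonize import HarmonizedInstrumentSet
from .iv_selection import (InstrumentStrength, SelectionConfig,
                           instrument_strength, select_instruments)
from .sensitivity import SensitivityReport, run_sensitivity


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    n_phenotypes: int = 206
    n_directions: int = 2
    alpha: float = 0.05
    bonferroni_override: float | None = None
    nominal_threshold: float = 1e-3
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    rng_seed: int | None = None
    presso_n_sim: int = 1000
    run_sensitivity: bool = True

    def __post_init__(self) -> None:
        bonf = self.bonferroni_threshold
        if self.nominal_threshold < bonf:
            raise PipelineError(
                f"nominal_threshold {self.nominal_threshold} below "
                f"Bonferroni threshold {bonf}"
            )

    @property
    def bonferroni_threshold(self) -> float:
        if self.bonferroni_override is not None:
            return self.bonferroni_override
        return self.alpha / (self.n_phenotypes * self.n_directions)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sel = SelectionConfig(**raw.pop("selection", {}))
        est = EstimatorConfig(**raw.pop("estimator", {}))
        return cls(selection=sel, estimator=est, **raw)


def significance_thresholds(config: PipelineConfig) -> tuple[float, float]:
    """(Bonferroni, nominal) thresholds; the Bonferroni value is
    alpha/(n_phenotypes · n_directions) unless explicitly overridden."""
    return config.bonferroni_threshold, config.nominal_threshold


@dataclass
class PowerQuery:
    """Inputs of the post-hoc power calculation.

    ``r2`` is the instrument set's variance explained on the exposure;
    ``effect`` is the hypothesized causal effect (log-OR for a binary
    outcome with case fraction ``case_fraction``)."""

    n: float
    r2: float
    effect: float
    alpha: float = 0.05
    case_fraction: float | None = None  # None -> continuous outcome

    def __post_init__(self) -> None:
        if not (0 < self.r2 < 1):
            raise PipelineError("r2 must be in (0,1)")
        if self.case_fraction is not None and not (0 < self.case_fraction < 1):
            raise PipelineError("case_fraction must be in (0,1)")


def power_calc(q: PowerQuery) -> float:
    """Approximate power of the two-sample MR test.

    Continuous outcome: Φ(√(n·r²)·|effect| − z_{1−α/2});
    binary outcome:     Φ(√(n·r²·K(1−K))·|effect| − z_{1−α/2}).
    """
    z_crit = stats.norm.ppf(1 - q.alpha / 2)
    if q.case_fraction is None:
        ncp = np.sqrt(q.n * q.r2) * abs(q.effect)
    else:
        kk = q.case_fraction
        ncp = np.sqrt(q.n * q.r2 * kk * (1 - kk)) * abs(q.effect)
    return float(stats.norm.cdf(ncp - z_crit))


@dataclass
class CausalLinkVerdict:
    pair: str
    direction: str  # "forward" | "reverse"
    n_iv: int
    ivw_pval: float | None
    tier: str  # "significant" | "nominal" | "null" | "not_evaluable"
    directions_consistent: bool
    sensitivity_clean: bool

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def assess_causal_link(
    estimates: dict[str, CausalEstimate],
    sensitivity: SensitivityReport | None,
    config: PipelineConfig,
    pair: str = "",
    direction: str = "forward",
) -> CausalLinkVerdict:
    """Apply the decision rule to one pair/direction.

    A pair with fewer than ``min_ivs`` instruments is not evaluable;
    direction consistency requires every method's estimate to share IVW's
    sign (an exactly-zero estimate counts as inconsistent)."""
    if "IVW-MRE" not in estimates:
        raise PipelineError("IVW estimate required for the decision rule")
    ivw = estimates["IVW-MRE"]
    bonf, nominal = significance_thresholds(config)
    if ivw.n_iv < config.selection.min_ivs:
        return CausalLinkVerdict(pair, direction, ivw.n_iv, ivw.pval,
                                 "not_evaluable", False, False)
    sign = np.sign(ivw.beta)
    consistent = bool(sign != 0) and all(
        np.sign(est.beta) == sign for est in estimates.values()
    )
    if ivw.pval < bonf:
        tier = "significant"
    elif ivw.pval < nominal:
        tier = "nominal"
    else:
        tier = "null"
    clean = sensitivity.clean() if sensitivity is not None else False
    return CausalLinkVerdict(pair, direction, ivw.n_iv, ivw.pval, tier,
                             consistent, clean)


@dataclass
class DirectionResult:
    direction: str
    exposure: str
    outcome: str
    estimates: dict[str, CausalEstimate]
    sensitivity: SensitivityReport | None
    strength: InstrumentStrength | None
    verdict: CausalLinkVerdict
    power: float | None
    audit: dict
    instruments: HarmonizedInstrumentSet | None


@dataclass
class BidirectionalResult:
    forward: DirectionResult
    reverse: DirectionResult

    def rows(self) -> list[dict]:
        out = []
        for d in (self.forward, self.reverse):
            for est in d.estimates.values():
                row = {"exposure": d.exposure, "outcome": d.outcome,
                       "direction": d.direction}
                row.update(est.as_row())
                out.append(row)
        return out

    def to_json(self) -> str:
        def enc(d: DirectionResult) -> dict:
            return {
                "direction": d.direction,
                "exposure": d.exposure,
                "outcome": d.outcome,
                "estimates": {m: e.as_row() | {"extras": _plain(e.extras)}
                              for m, e in d.estimates.items()},
                "verdict": d.verdict.as_dict(),
                "power": d.power,
                "audit": _plain(d.audit),
                "strength": None if d.strength is None else {
                    "r2_total": d.strength.r2_total, "f_stat": d.strength.f_stat,
                    "k": d.strength.k, "n": d.strength.n,
                },
                "sensitivity": None if d.sensitivity is None
                else _plain(d.sensitivity.verdict),
            }

        return json.dumps({"forward": enc(self.forward),
                           "reverse": enc(self.reverse)}, indent=2)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _run_direction(
    exposure: GwasSummaryTable,
    outcome: GwasSummaryTable,
    ld: LdReference,
    confounders: ConfounderSnpList | None,
    config: PipelineConfig,
    direction: str,
) -> DirectionResult:
    from .harmonize import HarmonizationError

    pair = f"{exposure.trait_name}->{outcome.trait_name}"
    try:
        hset, audit = select_instruments(exposure, outcome, ld, confounders,
                                         config.selection)
    except HarmonizationError:
        verdict = CausalLinkVerdict(pair, direction, 0, None,
                                    "not_evaluable", False, False)
        return DirectionResult(direction, exposure.trait_name,
                               outcome.trait_name, {}, None, None, verdict,
                               None, {"no_shared_instruments": True}, None)
    min_ivs = config.selection.min_ivs
    if hset.k < max(min_ivs, 3):
        # too few instruments to run the seven-method battery
        est = {}
        if hset.k >= 2:
            est["IVW-MRE"] = ivw_mre(hset)
        ivw_p = est["IVW-MRE"].pval if est else None
        verdict = CausalLinkVerdict(pair, direction, hset.k, ivw_p,
                                    "not_evaluable", False, False)
        return DirectionResult(direction, exposure.trait_name,
                               outcome.trait_name, est, None, None, verdict,
                               None, audit, hset)
    estimates = all_estimates(hset, config.estimator)
    sens = None
    if config.run_sensitivity:
        sens = run_sensitivity(
            hset, seed=config.rng_seed, n_sim=config.presso_n_sim,
            alpha=config.alpha, loo_threshold=config.nominal_threshold,
        )
    strength = instrument_strength(hset)
    verdict = assess_causal_link(estimates, sens, config, pair, direction)
    power = None
    if verdict.tier in ("significant", "nominal"):
        kf = None
        if outcome.trait_type == "binary":
            if outcome.case_fraction is not None:
                kf = outcome.case_fraction
            else:
                kf = float(np.nanmean(outcome.df["N_CASES"] / outcome.df["N"]))
        power = power_calc(PowerQuery(
            n=float(np.max(outcome.df["N"])), r2=strength.r2_total,
            effect=estimates["IVW-MRE"].beta, alpha=config.alpha,
            case_fraction=kf,
        ))
    return DirectionResult(direction, exposure.trait_name, outcome.trait_name,
                           estimates, sens, strength, verdict, power, audit,
                           hset)


def run_bidirectional_mr(
    exposure: GwasSummaryTable,
    outcome: GwasSummaryTable,
    ld: LdReference,
    confounders: ConfounderSnpList | None = None,
    config: PipelineConfig | None = None,
) -> BidirectionalResult:
    """Full bidirectional analysis: the selection cascade, all seven
    estimators, sensitivity diagnostics, instrument strength, the decision
    rule, and post-hoc power, in the forward direction and then with the
    roles swapped.  A direction whose cascade yields too few instruments is
    recorded as not evaluable, never raised."""
    config = config or PipelineConfig()
    if config.rng_seed is None:
        raise PipelineError(
            "pipeline runs must be seeded: set PipelineConfig.rng_seed"
        )
    if config.estimator.rng_seed is None:
        config = dataclasses.replace(
            config,
            estimator=dataclasses.replace(config.estimator,
                                          rng_seed=config.rng_seed),
        )
    fwd = _run_direction(exposure, outcome, ld, confounders, config, "forward")
    rev = _run_direction(outcome, exposure, ld, confounders, config, "reverse")
    return BidirectionalResult(forward=fwd, reverse=rev)
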