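"""Cross-model BIC comparison and the parameter-recovery harness.

BIC differences are read with the usual evidence convention: a difference
below 2 is inconclusive, 2-10 is positive evidence, and 10 or more is
strong evidence for the lower-scoring model.

The recovery harness is the package's main self-check at realistic scale:
it samples judgment data from a known plateau model at a study-scale
design, refits both the generating model class and the bare race, and
summarizes estimation error and how often the BIC prefers the generating
class.  Discrimination *between* the two plateau models is deliberately
reported rather than asserted: with similar curve shapes their BIC
differences are typically small.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import numpy as np

from .errors import FitFailureError, InconsistentComparisonError
from .fitting import FitOptions, FitResult, fit_model
from .models import MODELS, params_to_dict
from .synthetic import ExperimentDesign, sample_judgments

__all__ = ["ComparisonResult", "RecoverySummary", "compare_models",
           "evidence_label", "parameter_recovery"]

#: Strong-evidence threshold on a BIC difference.
STRONG_EVIDENCE_DELTA = 10.0
#: Below this a BIC difference is inconclusive (standard convention).
POSITIVE_EVIDENCE_DELTA = 2.0


def evidence_label(delta_bic: float) -> str:
    """Categorize an absolute BIC difference."""
    d = abs(delta_bic)
    if d >= STRONG_EVIDENCE_DELTA:
        return "strong"
    if d >= POSITIVE_EVIDENCE_DELTA:
        return "positive"
    return "inconclusive"


@dataclass(frozen=True)
class ComparisonResult:
    """Ranking of model fits on one dataset by BIC."""

    bic: dict                     # model -> BIC
    delta_bic: dict               # model -> BIC - min(BIC), >= 0
    preferred: str
    evidence: dict                # "modelA_vs_modelB" -> label
    n_trials: int

    def to_dict(self) -> dict:
        return {"bic": dict(self.bic), "delta_bic": dict(self.delta_bic),
                "preferred": self.preferred, "evidence": dict(self.evidence),
                "n_trials": self.n_trials}

    def table(self) -> str:
        """Human-readable comparison table."""
        lines = [f"{'model':<12} {'BIC':>12} {'dBIC':>10}"]
        for m in sorted(self.bic, key=self.bic.get):
            mark = " *" if m == self.preferred else ""
            lines.append(f"{m:<12} {self.bic[m]:>12.3f} {self.delta_bic[m]:>10.3f}{mark}")
        return "\n".join(lines)


def compare_models(fits: list[FitResult]) -> ComparisonResult:
    """Rank fits of different models on the same data by BIC.

    Ties in BIC break toward the fit listed first.  All fits must carry the
    same total trial count (the guard against comparing across datasets).
    """
    if not fits:
        raise InconsistentComparisonError("no fits to compare")
    n_trials = {f.n_trials for f in fits}
    if len(n_trials) != 1:
        raise InconsistentComparisonError(
            f"fits carry different trial counts {sorted(n_trials)}; "
            "BIC comparison requires the same data"
        )
    bics = {f.model: f.bic for f in fits}
    if len(bics) != len(fits):
        raise InconsistentComparisonError("duplicate model ids in comparison")
    best = min(fits, key=lambda f: f.bic).model
    delta = {m: b - bics[best] for m, b in bics.items()}
    evidence = {}
    models = [f.model for f in fits]
    for i, a in enumerate(models):
        for b in models[i + 1:]:
            evidence[f"{a}_vs_{b}"] = evidence_label(bics[a] - bics[b])
    return ComparisonResult(bic=bics, delta_bic=delta, preferred=best,
                            evidence=evidence, n_trials=n_trials.pop())


@dataclass(frozen=True)
class RecoverySummary:
    """Aggregate of a seeded parameter-recovery study."""

    model: str
    true_params: dict
    estimates: list                      # per-replicate flat param dicts
    median_abs_error: dict               # per-parameter |hat - true| medians
    frac_prefer_generating: float        # BIC vs the bare race
    delta_bic_vs_simple: list            # per-replicate BIC_simple - BIC_model
    n_replicates: int
    failures: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"model": self.model, "true_params": dict(self.true_params),
                "estimates": [dict(e) for e in self.estimates],
                "median_abs_error": dict(self.median_abs_error),
                "frac_prefer_generating": self.frac_prefer_generating,
                "delta_bic_vs_simple": list(self.delta_bic_vs_simple),
                "n_replicates": self.n_replicates,
                "failures": list(self.failures)}

    def table(self) -> str:
        lines = [f"recovery: {self.model} model, "
                 f"{len(self.estimates)}/{self.n_replicates} replicates fitted"]
        lines.append(f"{'param':<8} {'true':>10} {'median |err|':>14}")
        for name, err in self.median_abs_error.items():
            lines.append(f"{name:<8} {self.true_params[name]:>10.4f} {err:>14.4f}")
        lines.append(f"BIC prefers the {self.model} class over the bare race in "
                     f"{100 * self.frac_prefer_generating:.0f}% of replicates")
        return "\n".join(lines)


def parameter_recovery(model: str, true_params, design: ExperimentDesign,
                       n_replicates: int, options: FitOptions | None = None,
                       seed: int = 0) -> RecoverySummary:
    """Seeded recovery study: sample, fit, and summarize.

    For each replicate, judgment data is sampled from ``model`` at
    ``true_params`` on ``design``; then both the generating model and the
    bare race are refitted and their BICs compared.  Fit failures are
    recorded per replicate, never fatal.
    """
    if n_replicates < 1:
        raise InconsistentComparisonError(f"n_replicates must be >= 1, got {n_replicates}")
    if model not in MODELS:
        raise InconsistentComparisonError(f"unknown model {model!r}")
    truth = true_params if isinstance(true_params, dict) else params_to_dict(true_params)
    if options is None:
        options = FitOptions(fixed={"tau": 0.0})

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_replicates)
    estimates, deltas, failures = [], [], []
    prefer = 0
    for r in range(n_replicates):
        data = sample_judgments(model, truth, design, int(child_seeds[2 * r]))
        fit_options = FitOptions(
            n_starts=options.n_starts, bounds=options.bounds,
            fixed=options.fixed, seed=int(child_seeds[2 * r + 1] % (2 ** 31)),
            xatol=options.xatol, fatol=options.fatol, maxiter=options.maxiter,
        )
        try:
            fit_gen = fit_model(model, data, fit_options)
            fit_simple = fit_model("simple", data, fit_options)
        except FitFailureError as exc:
            failures.append({"replicate": r, "error": str(exc)})
            continue
        estimates.append(fit_gen.params)
        deltas.append(fit_simple.bic - fit_gen.bic)
        if fit_gen.bic < fit_simple.bic:
            prefer += 1

    free_names = [p for p in MODELS[model].param_names if p not in options.fixed]
    errors = {
        name: median(abs(e[name] - truth[name]) for e in estimates) if estimates else float("nan")
        for name in free_names
    }
    n_ok = len(estimates)
    return RecoverySummary(
        model=model,
        true_params=truth,
        estimates=estimates,
        median_abs_error=errors,
        frac_prefer_generating=prefer / n_ok if n_ok else float("nan"),
        delta_bic_vs_simple=deltas,
        n_replicates=n_replicates,
        failures=failures,
    )
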