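"""Secondary-antioxidant metrics, equilibrium speciation and report
assembly.

A chelator shows secondary antioxidant activity when its metal complex
is reduced by superoxide/ascorbate more slowly than the hydrated ion:
the fold-reduction is the ratio k_reference / k_complex. Speciation
distributes a total metal concentration over the free ion and its
1:1 ... 1:N complexes from cumulative (beta-style) formation constants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.optimize import brentq

from .errors import ConfigError, ConvergenceError
from .et_kinetics import RateResult
from .thermo import FormationResult, rank_stability

NEUTRAL_TOL = 0.05


@dataclass
class AntioxidantReport:
    """Fold-reductions of the reference reduction rate by each complex."""

    reference_rate: float
    complex_rates: dict[str, float]
    ratios: dict[str, float] = field(default_factory=dict)
    classification: dict[str, str] = field(default_factory=dict)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to the given number of significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def rate_ratio(k_reference: float, k_complex: float) -> float:
    """Fold-reduction k_reference / k_complex (> 1 means inhibition)."""
    if k_reference <= 0 or k_complex <= 0:
        raise ValueError("rate constants must be positive")
    return k_reference / k_complex


def classify_ratio(ratio: float, tol: float = NEUTRAL_TOL) -> str:
    """'inhibits' above 1 + tol, 'accelerates' below 1 - tol, else
    'neutral' (marginal ratios like 0.89-1.02 count as neutral only
    inside the band)."""
    if ratio > 1.0 + tol:
        return "inhibits"
    if ratio < 1.0 - tol:
        return "accelerates"
    return "neutral"


def antioxidant_report(
    reference_rate: float,
    complex_rates: Mapping[str, float],
    tol: float = NEUTRAL_TOL,
) -> AntioxidantReport:
    report = AntioxidantReport(
        reference_rate=reference_rate, complex_rates=dict(complex_rates)
    )
    for label, k in complex_rates.items():
        r = rate_ratio(reference_rate, k)
        report.ratios[label] = r
        report.classification[label] = classify_ratio(r, tol)
    return report


# ---------------------------------------------------------------------------
# speciation


@dataclass(frozen=True)
class Speciation:
    """Metal distribution over the free ion and 1:1 ... 1:N complexes."""

    free_ligand: float  # M
    fractions: tuple[float, ...]  # index 0 = free metal, i = 1:i complex

    def as_dict(self) -> dict[str, float]:
        out = {"free_metal": self.fractions[0]}
        for i, f in enumerate(self.fractions[1:], start=1):
            out[f"ML{i}"] = f
        return out


def cumulative_from_stepwise(stepwise_logK: Sequence[float]) -> list[float]:
    """Convert stepwise logK values to cumulative log(beta) values."""
    out, acc = [], 0.0
    for lk in stepwise_logK:
        acc += lk
        out.append(acc)
    return out


def speciation(
    metal_total: float,
    ligand_total: float,
    overall_logKf: Sequence[float],
    max_iter: int = 200,
) -> Speciation:
    """Solve the ligand mass balance for the free-ligand concentration.

    ``overall_logKf`` are cumulative formation constants log10(beta_i)
    for the 1:i complexes, i = 1..N. The free-ligand root is bracketed
    on [0, ligand_total] (the balance is monotone in L) and refined with
    Brent's method; fractions sum to 1 by construction.
    """
    if metal_total < 0 or ligand_total < 0:
        raise ValueError("total concentrations must be >= 0")
    if not overall_logKf:
        raise ValueError("overall_logKf must be non-empty")
    betas = [10.0 ** lk for lk in overall_logKf]

    def denominator(L: float) -> float:
        return 1.0 + sum(b * L**i for i, b in enumerate(betas, start=1))

    def bound_ligand(L: float) -> float:
        m_free = metal_total / denominator(L)
        return m_free * sum(i * b * L**i for i, b in enumerate(betas, start=1))

    if ligand_total == 0.0:
        L = 0.0
    else:
        def balance(L: float) -> float:
            return L + bound_ligand(L) - ligand_total

        try:
            L = brentq(
                balance, 0.0, ligand_total, xtol=1e-300, rtol=8.9e-16, maxiter=max_iter
            )
        except (ValueError, RuntimeError) as exc:
            raise ConvergenceError(
                f"free-ligand solve failed: {exc}; metal_total={metal_total}, "
                f"ligand_total={ligand_total}, logbeta={list(overall_logKf)}"
            ) from exc

    den = denominator(L)
    fractions = [1.0 / den] + [b * L**i / den for i, b in enumerate(betas, start=1)]
    return Speciation(free_ligand=L, fractions=tuple(fractions))


# ---------------------------------------------------------------------------
# report assembly


def report_dict(
    formation_results: Sequence[FormationResult] = (),
    rate_results: Sequence[RateResult] = (),
    groups: Mapping[str, tuple[str, str]] | None = None,
) -> dict:
    """Assemble the report as a plain dict (the JSON form).

    ``groups`` maps a formation-result label to (metal, ligand) so that
    per-metal stability orderings can be stated.
    """
    temps = {round(r.T, 9) for r in formation_results}
    if len(temps) > 1:
        raise ConfigError(f"mixed temperatures across formation results: {sorted(temps)}")

    formation_rows = [
        {
            "label": r.label,
            "delta_g_formation": r.delta_g_formation,
            "Kf": r.Kf,
            "logKf": r.logKf,
        }
        for r in formation_results
    ]
    rate_rows = [
        {
            "label": r.label,
            "delta_g_act": r.delta_g_act,
            "k_app": r.k_app,
            "diffusion_applied": r.diffusion_applied,
            "ratio_vs_reference": r.ratio_vs_reference,
        }
        for r in rate_results
    ]

    orderings: dict[str, str] = {}
    if groups:
        per_metal: dict[str, dict[str, float]] = {}
        for r in formation_results:
            if r.label in groups:
                metal, ligand = groups[r.label]
                best = per_metal.setdefault(metal, {})
                if ligand not in best or r.delta_g_formation < best[ligand]:
                    best[ligand] = r.delta_g_formation
        for metal, best in per_metal.items():
            orderings[metal] = " < ".join(rank_stability(best))

    return {
        "formation": formation_rows,
        "rates": rate_rows,
        "stability_order": orderings,
    }


def build_report(
    formation_results: Sequence[FormationResult] = (),
    rate_results: Sequence[RateResult] = (),
    fmt: str = "markdown",
    groups: Mapping[str, tuple[str, str]] | None = None,
) -> str:
    """Render the combined thermodynamics/kinetics report."""
    data = report_dict(formation_results, rate_results, groups)
    if fmt == "json":
        return json.dumps(data, indent=2)
    if fmt not in ("markdown", "tsv"):
        raise ConfigError(f"unknown report format {fmt!r}")

    lines: list[str] = []
    if fmt == "markdown":
        lines.append("## Formation thermodynamics")
        lines.append("| label | dGf (kcal/mol) | Kf | logKf |")
        lines.append("| --- | --- | --- | --- |")
        for row in data["formation"]:
            lines.append(
                f"| {row['label']} | {row['delta_g_formation']:.1f} "
                f"| {row['Kf']:.3g} | {row['logKf']:.2f} |"
            )
        for metal, order in data["stability_order"].items():
            lines.append(f"\nStability order ({metal}): {order}")
        lines.append("\n## Reduction kinetics")
        lines.append("| label | dG_act (kcal/mol) | k_app (1/M/s) | ratio |")
        lines.append("| --- | --- | --- | --- |")
        for row in data["rates"]:
            ratio = row["ratio_vs_reference"]
            ratio_s = f"{round_sig(ratio, 3):.3g}" if ratio is not None else ""
            lines.append(
                f"| {row['label']} | {row['delta_g_act']:.2f} "
                f"| {row['k_app']:.3g} | {ratio_s} |"
            )
    else:  # tsv
        lines.append("label\tdelta_g_formation\tKf\tlogKf")
        for row in data["formation"]:
            lines.append(
                f"{row['label']}\t{row['delta_g_formation']:.1f}"
                f"\t{row['Kf']:.3g}\t{row['logKf']:.2f}"
            )
        for metal, order in data["stability_order"].items():
            lines.append(f"# stability order ({metal}): {order}")
        lines.append("label\tdelta_g_act\tk_app\tratio_vs_reference")
        for row in data["rates"]:
            ratio = row["ratio_vs_reference"]
            ratio_s = f"{round_sig(ratio, 3):.3g}" if ratio is not None else ""
            lines.append(
                f"{row['label']}\t{row['delta_g_act']:.2f}\t{row['k_app']:.3g}\t{ratio_s}"
            )
    return "\n".join(lines) + "\n"
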