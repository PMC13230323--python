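"""Cost-benefit model: conventional phenotypic selection vs GS-assisted
selection with GBS genotyping.

Phenotyping a line in a preliminary yield trial costs
plots_per_line * plot_cost for field plots plus, per lab replication, an oil
profile (FAME) assay and a disease-screening row.  GBS genotyping cost per
sample is linear in targeted sequencing depth, y = a*x + b CAD with x in
millions of PE150 reads, truncated (not rounded) to cents.  A GS-assisted
program genotypes every candidate line but field-phenotypes only the lines
advanced by genomic pre-selection.

All money is handled as exact integer cents (Fractions internally), so
scenario totals carry no floating-point drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction


class CostParameterError(ValueError):
    pass


def _frac(x) -> Fraction:
    # via str() so float literals like 1.3594 mean their decimal reading
    return Fraction(str(x))


def _floor_cents(x: Fraction) -> int:
    return int(x * 100 // 1)


def _round_half_away_int(x: Fraction) -> int:
    if x >= 0:
        return int((x + Fraction(1, 2)) // 1)
    return -int((-x + Fraction(1, 2)) // 1)


@dataclass
class CostParams:
    plot_cost: float = 75.0  # CAD per field plot
    plots_per_line: int = 2
    fame_cost: float = 10.0  # CAD per sample, oil profile by GC
    disease_cost: float = 12.50  # CAD per row, disease screening
    reps_for_lab: int = 2  # lab assays counted per replication
    seq_slope: float = 1.3594  # CAD per million PE150 reads
    seq_intercept: float = 17.121  # CAD, DNA prep + library
    currency: str = "CAD"

    def __post_init__(self) -> None:
        for name in (
            "plot_cost",
            "plots_per_line",
            "fame_cost",
            "disease_cost",
            "reps_for_lab",
            "seq_slope",
            "seq_intercept",
        ):
            if _frac(getattr(self, name)) < 0:
                raise CostParameterError(f"{name} must be >= 0")


def per_sample_gbs_cost(x: float, params: CostParams | None = None) -> float:
    """GBS cost per sample at x million reads: a*x + b, floored to cents."""
    p = params or CostParams()
    if _frac(x) <= 0:
        raise CostParameterError("read depth x must be > 0")
    cents = _floor_cents(_frac(p.seq_slope) * _frac(x) + _frac(p.seq_intercept))
    return cents / 100.0


def per_line_pheno_cost(params: CostParams | None = None) -> float:
    """Per-line phenotyping: plots plus per-replication lab assays."""
    p = params or CostParams()
    cents = _floor_cents(
        _frac(p.plots_per_line) * _frac(p.plot_cost)
        + _frac(p.reps_for_lab) * (_frac(p.fame_cost) + _frac(p.disease_cost))
    )
    return cents / 100.0


@dataclass
class CostScenario:
    n_lines: int
    reads_per_sample: float
    reduction_percent_range: tuple[float, float]
    per_line_pheno: float
    per_sample_genotyping: float
    conventional_total: float
    genotyping_total: float
    advanced_lines: tuple[int, int]  # at (high, low) reduction
    gs_totals: tuple[float, float]  # (low-cost at high reduction, high-cost at low)
    savings_percent: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "n_lines": self.n_lines,
            "reads_per_sample": self.reads_per_sample,
            "reduction_percent_range": list(self.reduction_percent_range),
            "per_line_pheno": self.per_line_pheno,
            "per_sample_genotyping": self.per_sample_genotyping,
            "conventional_total": self.conventional_total,
            "genotyping_total": self.genotyping_total,
            "advanced_lines": list(self.advanced_lines),
            "gs_totals": list(self.gs_totals),
            "savings_percent": list(self.savings_percent),
        }


def scenario(
    n_lines: int,
    x: float,
    reduction_percent_range: tuple[float, float],
    params: CostParams | None = None,
) -> CostScenario:
    """Conventional vs GS-assisted totals over a reduction range.

    conventional = n_lines * per-line phenotyping; GS-assisted(r) =
    genotyping everyone + phenotyping only the advanced
    round(n_lines * (1 - r/100)) lines; savings are relative to conventional,
    nearest-integer percent.
    """
    p = params or CostParams()
    r_lo, r_hi = sorted(reduction_percent_range)
    for r in (r_lo, r_hi):
        if not 0 <= r <= 100:
            raise CostParameterError(f"reduction {r} outside [0, 100]")
    pheno_cents = _frac(per_line_pheno_cost(p)) * 100
    geno_cents = _frac(per_sample_gbs_cost(x, p)) * 100
    conventional = n_lines * pheno_cents
    genotyping = n_lines * geno_cents
    if conventional == 0:
        raise CostParameterError(
            "conventional program cost is zero; savings are undefined"
        )

    def advanced(r) -> int:
        return _round_half_away_int(_frac(n_lines) * (1 - _frac(r) / 100))

    def gs_total_cents(r) -> Fraction:
        return genotyping + advanced(r) * pheno_cents

    def savings(r) -> int:
        return _round_half_away_int(
            100 * (conventional - gs_total_cents(r)) / conventional
        )

    return CostScenario(
        n_lines=n_lines,
        reads_per_sample=x,
        reduction_percent_range=(r_lo, r_hi),
        per_line_pheno=per_line_pheno_cost(p),
        per_sample_genotyping=per_sample_gbs_cost(x, p),
        conventional_total=int(conventional) / 100.0,
        genotyping_total=int(genotyping) / 100.0,
        advanced_lines=(advanced(r_hi), advanced(r_lo)),
        gs_totals=(int(gs_total_cents(r_hi)) / 100.0, int(gs_total_cents(r_lo)) / 100.0),
        savings_percent=(savings(r_hi), savings(r_lo)),
    )


def break_even_reduction(n_lines: int, x: float, params: CostParams | None = None) -> float:
    """Reduction percent r* at which GS-assisted cost equals conventional:
    genotyping = (r*/100) * conventional (exact rational arithmetic)."""
    p = params or CostParams()
    conventional = _frac(n_lines) * _frac(per_line_pheno_cost(p))
    genotyping = _frac(n_lines) * _frac(per_sample_gbs_cost(x, p))
    if conventional == 0:
        raise CostParameterError("conventional cost is zero; no break-even")
    return float(100 * genotyping / conventional)
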