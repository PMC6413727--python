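"""Leave-one-out sensitivity analysis and funnel-plot data.

Leave-one-out re-pools the IVW estimate k times, dropping one SNP each
time; a pooled result that barely moves under any single removal is not
driven by one influential variant. The funnel data pair each SNP's ratio
estimate with its precision; asymmetry about the pooled estimate suggests
directional pleiotropy.
"""

from __future__ import annotations

from .estimators import ivw_estimate
from .records import (
    FunnelPoint,
    InsufficientInstrumentsError,
    LeaveOneOutRow,
    MREstimate,
    WaldRatio,
)


def leave_one_out(
    ratios: list[WaldRatio], model: str = "fixed"
) -> list[LeaveOneOutRow]:
    """One IVW re-estimate per dropped SNP, with relative OR shift.

    ``model`` is applied to every re-fit (the full-fit model type, not
    per-row re-selection) so all rows are comparable against the same
    baseline. ``delta_rel`` is (OR_dropped - OR_full) / OR_full.
    """
    if len(ratios) < 3:
        raise InsufficientInstrumentsError(
            f"leave-one-out needs >= 3 ratios, got {len(ratios)}"
        )
    full, _ = ivw_estimate(ratios, model=model)
    or_full = full.odds_ratio
    rows = []
    for j, dropped in enumerate(ratios):
        subset = ratios[:j] + ratios[j + 1 :]
        est, het = ivw_estimate(subset, model=model)
        rows.append(
            LeaveOneOutRow(
                dropped_snp=dropped.snp_id,
                estimate=est,
                heterogeneity=het,
                delta_rel=(est.odds_ratio - or_full) / or_full,
            )
        )
    return rows


def funnel_data(
    ratios: list[WaldRatio], pooled: MREstimate
) -> tuple[list[FunnelPoint], float]:
    """Per-SNP (ratio, precision) points plus the pooled reference line.

    No smoothing or binning: the returned points are the plot contract, the
    reference is the pooled log-OR as a vertical line position.
    """
    if not ratios:
        raise InsufficientInstrumentsError("funnel data needs at least one ratio")
    points = [
        FunnelPoint(snp_id=r.snp_id, beta_xy=r.beta_xy, precision=1.0 / r.se_xy)
        for r in ratios
    ]
    return points, pooled.beta
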