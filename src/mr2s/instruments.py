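"""Instrument selection: significance filtering, LD clumping, outcome exclusion.

The pipeline mirrors the standard two-sample MR workflow: keep genome-wide
significant exposure SNPs, greedily clump them by P-value rank so the
retained set is approximately independent, then drop SNPs with evidence of a
direct outcome association (known loci or nominally significant outcome P).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .records import ConfigError, HarmonizedInstrument, LDPair, SelectionReport

log = logging.getLogger(__name__)


def read_ld_table(path: str | Path) -> list[LDPair]:
    """Read a pairwise LD table (tab-separated: snp_a, snp_b, r2)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    for col in ("snp_a", "snp_b", "r2"):
        if col not in df.columns:
            raise ConfigError(f"LD table {path} missing column {col!r}")
    return [
        LDPair(snp_a=r.snp_a, snp_b=r.snp_b, r2=float(r.r2))
        for r in df.itertuples()
    ]


def filter_by_exposure_p(
    instruments: list[HarmonizedInstrument], threshold: float = 5e-8
) -> list[HarmonizedInstrument]:
    """Keep instruments with exposure P strictly below ``threshold``."""
    if not (0 < threshold <= 1) and threshold != 0:
        raise ConfigError(f"exposure P threshold {threshold} outside [0, 1]")
    return [v for v in instruments if v.pval_exposure < threshold]


def _ld_lookup(ld: list[LDPair] | None) -> dict[frozenset, float]:
    table: dict[frozenset, float] = {}
    for pair in ld or []:
        key = frozenset((pair.snp_a, pair.snp_b))
        table[key] = max(pair.r2, table.get(key, 0.0))
    return table


def _clump_rank_key(v: HarmonizedInstrument):
    # P-value rank; ties broken by (chrom, pos) then rsID for determinism
    return (v.pval_exposure, v.chrom, v.pos, v.snp_id)


def ld_clump(
    instruments: list[HarmonizedInstrument],
    ld: list[LDPair] | None = None,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> tuple[list[HarmonizedInstrument], SelectionReport]:
    """Greedy P-value-ranked clumping by LD and physical distance.

    Instruments are processed in ascending exposure-P order; each accepted
    SNP discards any remaining SNP with r2 > ``r2_max`` against it, or on the
    same chromosome strictly within ``window_kb`` kilobases of it. Pairs
    absent from the LD table are treated as unlinked (r2 = 0). Survivors are
    returned in genomic order with a report of each removal and its trigger.
    """
    if not (0.0 <= r2_max <= 1.0):
        raise ConfigError(f"r2_max {r2_max} outside [0, 1]")
    if window_kb < 0:
        raise ConfigError(f"negative clumping window {window_kb}")
    r2 = _ld_lookup(ld)
    window_bp = window_kb * 1000.0

    report = SelectionReport(n_input=len(instruments))
    pending = sorted(instruments, key=_clump_rank_key)
    kept: list[HarmonizedInstrument] = []
    while pending:
        top = pending.pop(0)
        kept.append(top)
        survivors = []
        for v in pending:
            pair_r2 = r2.get(frozenset((top.snp_id, v.snp_id)), 0.0)
            if pair_r2 > r2_max:
                report.removed.append(
                    (v.snp_id, f"LD r2={pair_r2:g} > {r2_max:g} with {top.snp_id}")
                )
            elif v.chrom == top.chrom and abs(v.pos - top.pos) < window_bp:
                report.removed.append(
                    (
                        v.snp_id,
                        f"within {window_kb:g} kb of {top.snp_id} "
                        f"(|dpos|={abs(v.pos - top.pos)} bp)",
                    )
                )
            else:
                survivors.append(v)
        pending = survivors
    kept.sort(key=lambda v: (v.chrom, v.pos, v.snp_id))
    report.n_after_clump = len(kept)
    for snp, reason in report.removed:
        log.info("clump removed %s: %s", snp, reason)
    return kept, report


def exclude_outcome_associated(
    instruments: list[HarmonizedInstrument],
    known_loci: list[str] | None = None,
    outcome_p_min: float = 0.05,
) -> tuple[list[HarmonizedInstrument], SelectionReport]:
    """Drop instruments with evidence of a direct outcome association.

    Removes SNPs named in ``known_loci``, then SNPs with outcome P strictly
    below ``outcome_p_min`` (strict, so a SNP at exactly the threshold
    survives).
    """
    if not (0 < outcome_p_min <= 1):
        raise ConfigError(f"outcome P threshold {outcome_p_min} outside (0, 1]")
    known = set(known_loci or [])
    report = SelectionReport(n_input=len(instruments))

    after_known = []
    for v in instruments:
        if v.snp_id in known:
            report.removed.append((v.snp_id, "known outcome-associated locus"))
        else:
            after_known.append(v)
    report.n_after_known_outcome_loci = len(after_known)

    kept = []
    for v in after_known:
        if v.pval_outcome < outcome_p_min:
            report.removed.append(
                (v.snp_id, f"outcome P={v.pval_outcome:g} < {outcome_p_min:g}")
            )
        else:
            kept.append(v)
    report.n_after_outcome_p = len(kept)
    return kept, report


def select_instruments(
    instruments: list[HarmonizedInstrument],
    p_exposure: float = 5e-8,
    ld: list[LDPair] | None = None,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000,
    known_loci: list[str] | None = None,
    p_outcome: float = 0.05,
    extra_exclusions: list[str] | None = None,
    clump: bool = True,
) -> tuple[list[HarmonizedInstrument], SelectionReport]:
    """Run the full selection pipeline and reconcile its bookkeeping.

    Order: exposure-significance filter, LD clump, user-supplied exclusions
    (e.g. SNPs removed for reasons external to these rules), known outcome
    loci, outcome-P filter. The report accounts for every input SNP exactly
    once as survivor or removal.

    Set ``clump=False`` for tables that are already LD-pruned: without the
    original reference panel the distance backstop would spuriously discard
    independent same-chromosome loci that genuine r2 data had cleared.
    """
    report = SelectionReport(n_input=len(instruments))

    sig = filter_by_exposure_p(instruments, p_exposure)
    sig_ids = {v.snp_id for v in sig}
    for v in instruments:
        if v.snp_id not in sig_ids:
            report.removed.append(
                (v.snp_id, f"exposure P={v.pval_exposure:g} >= {p_exposure:g}")
            )
    report.n_after_significance = len(sig)

    if clump:
        clumped, clump_report = ld_clump(sig, ld, clump_r2, clump_kb)
        report.removed.extend(clump_report.removed)
        report.n_after_clump = len(clumped)
    else:
        clumped = sig

    if extra_exclusions:
        extra = set(extra_exclusions)
        kept = [v for v in clumped if v.snp_id not in extra]
        for v in clumped:
            if v.snp_id in extra:
                report.removed.append((v.snp_id, "user-supplied exclusion"))
        clumped = kept

    final, out_report = exclude_outcome_associated(clumped, known_loci, p_outcome)
    report.removed.extend(out_report.removed)
    report.n_after_known_outcome_loci = out_report.n_after_known_outcome_loci
    report.n_after_outcome_p = out_report.n_after_outcome_p

    assert report.n_final == len(final), "selection bookkeeping out of balance"
    return final, report
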