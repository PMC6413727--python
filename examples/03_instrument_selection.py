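"""Instrument selection on synthetic data with a pairwise LD table.

Generates a two-sample dataset with known truth, plants one LD-linked pair
and one physically close pair, then runs the selection pipeline:
genome-wide-significance filter, greedy P-ranked LD clump, and
outcome-association exclusion.
"""

import dataclasses

import mr2s
from mr2s.simulate import SimulationConfig

exposure, outcome, truth = mr2s.generate_summary_stats(
    SimulationConfig(n_snps=12, true_effect=0.4, seed=20)
)
# put rs2 next to rs1 (same chromosome, 2 Mb apart) to trip the distance rule
exposure[1] = dataclasses.replace(exposure[1], chrom="1", pos=3_000_000)
outcome[1] = dataclasses.replace(outcome[1], chrom="1", pos=3_000_000)
instruments = mr2s.harmonize_pair(exposure, outcome)

ld = [mr2s.LDPair("rs3", "rs10", 0.4)]  # cross-chromosome proxy pair
selected, report = mr2s.select_instruments(
    instruments,
    p_exposure=5e-8,
    ld=ld,
    clump_r2=0.001,
    clump_kb=10_000,
    known_loci=["rs2"],
    p_outcome=0.05,
)

print(f"input SNPs:             {report.n_input}")
print(f"after P < 5e-8:         {report.n_after_significance}")
print(f"after LD clump:         {report.n_after_clump}")
print(f"after known-loci drop:  {report.n_after_known_outcome_loci}")
print(f"after outcome-P filter: {report.n_after_outcome_p}\n")
for snp, reason in report.removed:
    print(f"removed {snp}: {reason}")

est, _ = mr2s.ivw_estimate(mr2s.wald_ratios(selected), model="fixed")
print(
    f"\nIVW on the {len(selected)} survivors: log-OR {est.beta:.3f} "
    f"(truth {truth.theta}), OR {est.odds_ratio:.3f}"
)
print(
    "\nReading: the clump keeps the most significant SNP of each linked or"
    "\nnearby group, the exclusion stages enforce the no-direct-effect"
    "\nassumption, and the surviving set still recovers the simulated effect."
)
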