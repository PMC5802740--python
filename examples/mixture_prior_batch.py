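"""Mixture Bayes intervals from a tabulated odds-ratio prior.

Builds a synthetic L-shaped effect-size distribution (most loci null, a
thin tail of real effects), turns it into a discrete prior on the
standardized effect size, and reports 95% prediction intervals for a small
study table by three methods.
"""

import tempfile
from pathlib import Path

from pintervals import (
    batch_intervals,
    estimate_prior_variance_from_counts,
    generate_fixtures,
    read_prior_table,
    read_study_table,
)

with tempfile.TemporaryDirectory() as tmp:
    paths = generate_fixtures(seed=7, outdir=Path(tmp))
    table = read_prior_table(paths["prior_table"])
    rows = read_study_table(paths["study_table"])

    s0_sq = estimate_prior_variance_from_counts(table, effective_n=1000.0)
    print(f"prior variance implied by the OR table: s0^2 = {s0_sq:.3g}")
    # Genome-scale effect-size tables imply s0^2 of order 1e-5: the prior
    # on the standardized effect is extremely concentrated near zero.

    report = batch_intervals(rows, s0_sq=s0_sq, prior_table=table, level=0.95)
    print(f"\n{'study':<10} {'method':<11} {'p_lower':>10} {'p_upper':>10}")
    for r in report:
        print(f"{r.label:<10} {r.method:<11} {r.p_lower:>10.3g} "
              f"{r.p_upper:>10.3g}")
# The classical rows predict implausibly tiny replication P-values for
# every study; the Bayesian rows, informed by the realistic prior, keep
# the lower bounds orders of magnitude higher.
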