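"""Helpers shared by test modules."""

import numpy as np

from sedascope.authdamage import DamageProfile, LengthSummary, TaxonProfile


def profile_with_terminals(n_reads=200, t5=0.3, t3=0.3, mean_cov=10.0, K=15):
    """TaxonProfile with prescribed terminal damage rates (denominators 100)."""
    f5 = np.full(K, np.nan)
    f3 = np.full(K, np.nan)
    d5 = np.zeros(K, dtype=int)
    d3 = np.zeros(K, dtype=int)
    if t5 is not None:
        f5[0], d5[0] = t5, 100
    if t3 is not None:
        f3[0], d3[0] = t3, 100
    return TaxonProfile(
        taxon_id="sp",
        n_reads=n_reads,
        damage=DamageProfile(f5, f3, d5, d3),
        lengths=LengthSummary.empty(),
        mean_coverage=mean_cov,
    )
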