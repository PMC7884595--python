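"""Calibration studies for the CIF detection pipeline.

These run the full estimation pipeline on synthetic data with known ground
truth and measure its operating characteristics: sensitivity and empirical
false discovery proportion on planted features, and the uniformity of
permutation p-values under the null.  They are used by the test suite and
the reproduction script; the study conditions (gene counts, noise rates,
permutation counts) are fixed choices documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kstest

from .cif import (count_features, estimate_cifs, permutation_pvalues,
                  significant_cifs, site_name)
from .synth import PlantedCif, SynthConfig, simulate_gene_set

#: Planted paired-site features for the recovery study: two mis-pairs and
#: two pairs at stem coordinates, each private to one or two classes.
RECOVERY_PLANTINGS = (
    PlantedCif(("1", "72"), "UA", ("D", "E")),
    PlantedCif(("13", "22"), "UU", ("P", "V")),
    PlantedCif(("31", "39"), "UU", ("M",)),
    PlantedCif(("50", "64"), "CU", ("I",)),
)


@dataclass
class RecoveryResult:
    sensitivity: float          # mean fraction of planted features recovered
    empirical_fdr: float        # mean fraction of reported features unplanted
    n_seeds: int
    per_seed_sensitivity: list[float]
    per_seed_fdp: list[float]


def planted_recovery_study(seed: int, n_seeds: int = 20,
                           gene_copies: int = 8, permutations: int = 999,
                           fdr: float = 0.05,
                           background_rate: float = 0.02) -> RecoveryResult:
    """Plant four paired-site CIFs at full penetrance and measure recovery.

    Class consensuses are identical (divergence zero), so the planted
    features are the only class-specific signal.  A planting at full
    penetrance necessarily induces one complementary true feature per
    planted site: the shared consensus state there is carried by every gene
    *except* those of the planted classes, so it genuinely informs against
    them.  Ground truth therefore comprises the planted states and, at each
    planted site, the consensus state among non-planted classes; sensitivity
    is measured on the planted states alone, and every other significant
    feature counts as a false discovery.  Replicated over ``n_seeds``
    independent data sets with sub-seeds derived from ``seed``.
    """
    sens, fdp = [], []
    planted_keys = {(site_name(p.site), p.state) for p in RECOVERY_PLANTINGS}
    for i in range(n_seeds):
        sub = int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
                  % (2 ** 31))
        cfg = SynthConfig(seed=sub, gene_copies=gene_copies,
                          class_divergence=0.0,
                          background_rate=background_rate, gap_rate=0.0,
                          planted_cifs=RECOVERY_PLANTINGS)
        aln, _, _ = simulate_gene_set(cfg)
        truth = set(planted_keys)
        for p in RECOVERY_PLANTINGS:
            fct = count_features(aln, p.site)
            others = {x: n for x, n in
                      ((x, fct.n_genes(x)) for x in fct.states)
                      if n > 0 and x != p.state}
            if others:
                complement = max(sorted(others), key=others.get)
                truth.add((site_name(p.site), complement))
        table = estimate_cifs(aln, include_singles=False, include_pairs=True,
                              estimator="plugin", permutations=permutations,
                              seed=sub + 1)
        sig = significant_cifs(table, fdr=fdr)
        found = {(site_name(e.site), e.state) for e in sig.entries}
        sens.append(len(found & planted_keys) / len(planted_keys))
        fdp.append(len(found - truth) / len(found) if found else 0.0)
    return RecoveryResult(float(np.mean(sens)), float(np.mean(fdp)),
                          n_seeds, sens, fdp)


@dataclass
class CalibrationResult:
    ks_distance: float
    n_features: int
    p_values: np.ndarray


def null_pvalue_calibration(seed: int, n_features: int = 500,
                            permutations: int = 1000,
                            gene_copies: int = 8,
                            min_carriers: int = 5) -> CalibrationResult:
    """Permutation p-value uniformity when labels are independent of features.

    Simulates alignments in which every site is drawn independently from the
    base composition for every gene (class divergence zero, substitution
    rate one), so each single-site state is carried by an exchangeable
    random gene subset and is exactly null.  Permutation p-values are
    computed for all features carried by at least ``min_carriers`` genes —
    below that the permutation distribution is too discrete for a
    meaningful uniformity check — and the Kolmogorov-Smirnov distance of
    the pooled p-values from the uniform distribution is returned.  For a
    perfectly calibrated test the distance behaves like the KS statistic of
    uniform draws (median about 0.83/sqrt(n_features)).
    """
    pvals: list[float] = []
    stream = 0
    while len(pvals) < n_features:
        sub = int(np.random.SeedSequence([seed, 777, stream])
                  .generate_state(1)[0] % (2 ** 31))
        stream += 1
        cfg = SynthConfig(seed=sub, gene_copies=gene_copies,
                          class_divergence=0.0, background_rate=1.0,
                          gap_rate=0.0)
        aln, _, _ = simulate_gene_set(cfg)
        pmap = permutation_pvalues(aln, list(aln.sprinzl.labels),
                                   B=permutations, seed=sub + 1,
                                   estimator="plugin")
        for (site, state), p in sorted(pmap.items()):
            fct = count_features(aln, site)
            if fct.n_genes(state) >= min_carriers:
                pvals.append(p)
    arr = np.array(pvals[:n_features])
    ks = float(kstest(arr, "uniform").statistic)
    return CalibrationResult(ks, len(arr), arr)
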