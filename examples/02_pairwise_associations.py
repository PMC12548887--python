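"""Pairwise dependence with permutation significance on pairwise-complete data.

Compares a planted chain pair (shares a latent factor, population r = 0.49)
with a null pair. MI is the plug-in binned estimate in nats; NMI its
geometric-mean normalisation; p-values come from 1000 label permutations
(one-tailed for MI, two-tailed for Pearson).
"""

from cohortnet import default_cohort_spec, generate_cohort, pair_association

table = generate_cohort(default_cohort_spec(n_subjects=2000, seed=1))

for a, b, label in [
    ("genetic_004", "PET_008", "chain pair (dependent)"),
    ("genetic_000", "MRI_009", "null pair (independent)"),
]:
    res = pair_association(
        table.data[a], table.data[b], var_a=a, var_b=b,
        discrete=(table.is_discrete(a), table.is_discrete(b)),
        n_perm=1000, seed=1,
    )
    print(f"{label}: {a} vs {b}")
    print(f"  n_complete={res.n_complete}  mi={res.mi:.4f} nats  "
          f"nmi={res.nmi:.4f}  r={res.r:+.4f}")
    print(f"  p_mi={res.p_mi:.4f}  p_r={res.p_r:.4f}")
# The chain pair should be significant under both tests (p ~ 1/1001); the
# null pair's p-values are draws from ~Uniform(0, 1).
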