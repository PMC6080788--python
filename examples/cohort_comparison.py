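"""Family-weighted comparison of two protein cohorts.

Builds a 'peripheral-like' cohort whose protrusions are hydrophobic with
probability 0.5 and a 'reference-like' cohort with probability 0.2, then
compares the weighted fraction of hydrophobes on protrusions with the log
odds ratio, and the observed co-insertion fraction with its permutation
null (hydrophobes reshuffled over each protein's protrusion positions).
"""

import math

import perihull as ph
from perihull import stats

spec_a = ph.FixtureSpec(n_spikes=12, n_families=30, seed=1, hydrophobe_placement=0.5)
spec_b = ph.FixtureSpec(n_spikes=12, n_families=30, seed=2, hydrophobe_placement=0.2)
cohort_a, _ = ph.make_cohort(spec_a, name="peripheral-like")
cohort_b, _ = ph.make_cohort(spec_b, name="reference-like")

fa = ph.weighted_fraction(cohort_a, stats.hydrophobe, stats.protrusion)
fb = ph.weighted_fraction(cohort_b, stats.hydrophobe, stats.protrusion)
lnr = ph.odds_ratio(fa, fb)
print(f"F[hydrophobe|protrusion] A = {fa.estimate:.3f} [{fa.lower:.3f}, {fa.upper:.3f}]")
print(f"F[hydrophobe|protrusion] B = {fb.estimate:.3f} [{fb.lower:.3f}, {fb.upper:.3f}]")
print(
    f"ln R(A,B) = {lnr.estimate:.3f} [{lnr.lower:.3f}, {lnr.upper:.3f}] "
    f"(planted truth ln 4 = {math.log(4):.3f}; positive = enriched in A)"
)

pc = ph.pair_counts(cohort_a)
print(
    f"\ncohort A co-insertable pairs: N one-hydrophobe = {pc.n_pair_one:.1f}, "
    f"N both = {pc.n_pair_both:.1f}, F[both|one] = {pc.f_both_given_one.estimate:.3f}"
)
null = ph.co_insertion_comparison(cohort_a, n_samples=500, seed=3)
r = null["ln_r"]
print(
    f"observed vs permutation null ln R = {r.estimate:.3f} "
    f"[{r.lower:.3f}, {r.upper:.3f}] — near 0 here because the fixture plants "
    "hydrophobes at random, i.e. no genuine co-insertion clustering"
)

rows = ph.density_range_comparison(cohort_a, cohort_b, [(0, 6), (6, 14), (14, 22)])
print("\nhydrophobe enrichment on vertex residues by local density range:")
for row in rows:
    r = row["ln_r"]
    label = f"{row['range'][0]:>2}<d<={row['range'][1]}"
    if r.undefined:
        print(f"  {label}: undefined (empty range in one cohort)")
    else:
        print(f"  {label}: ln R = {r.estimate:+.3f} [{r.lower:+.3f}, {r.upper:+.3f}]")
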