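# permtest

Exact permutation and random-transformation tests, built on the group
structure that makes them valid.

A test statistic `T` and a finite group `G` of data transformations (index
permutations, sign flips, or rotations) define a test of the null hypothesis
that the joint distribution of `(T(gX))_{g in G}` is invariant under `G`.
This package implements the whole family of such tests and their p-values:

* **Full-group test** — reject when `T(x)` strictly exceeds the order
  statistic `T^{(k)}` over all of `G`, `k = ceil((1-alpha)#G)`. Level at
  most `alpha`; under an equal-class structure of the statistic the
  rejection probability is exactly `floor(alpha*m)/m`.
* **Boundary-randomized (Hoeffding) test** — rejects with probability
  `a = (alpha#G - M+)/M0` at the tie `T(x) = T^{(k)}`; exactly level
  `alpha`, ties or not.
* **Random-transformation test** — `w - 1` random draws from `G` plus the
  identity in position 1; level at most `alpha`. Its boundary-randomized
  version is exactly level `alpha`.
* **Representative sampling** — draws one canonical representative per
  statistic-equivalence class of the two-sample design; without replacement
  the test is exact for `alpha` in `{0/w, ..., (w-1)/w}`.
* **Subset-shift test** — for a finite subset `G*` of a possibly infinite
  group, compares `T(x)` against `T` over `G* h^{-1}` with `h` uniform on
  `G*`; level at most `alpha` (2-D rotation designs included).
* **Monte Carlo test** — iid draws from a fully specified null, included
  for contrast with the conditional (orbit-based) permutation tests.
* **P-values** — the full-group `D/#G`; the safe `(B+1)/(w+1)`; the
  randomized `p'` (exactly uniform under the null); its upper bound; and the
  naive `B/w`, which is deliberately hard to obtain because it is not a
  valid p-value on its own.

Non-groups break all of this: the balanced-permutation negative control
(`permtest demo balanced`) shows the type-I error inflation empirically, and
test functions refuse uncertified transformation sets unless explicitly
overridden.

## Library example

```python
import numpy as np
import permtest as pt

x = np.array([1.1, 2.3, 0.4, 1.8, 0.9, 2.6])

# full-group sign-flip test
G = pt.sign_flip_group_set(6)
result = pt.full_group_test(x, G, pt.sum_statistic, alpha=0.05)

# random draws with the identity adjoined, and the safe p-value
drawn = pt.draw_transformations(pt.SignFlipGroup(6), w=1000,
                                scheme="with_replacement", rng=7)
report = pt.report_from_draws(x, drawn, pt.sum_statistic)
print(result.reject, report.p_plus_one)
```

## Command line

```bash
# random sign-flip test on a one-column CSV (value)
permtest test --input data.csv --w 999 --alpha 0.05 --seed 7

# two-sample file (value,group with two equal-sized levels), full group
permtest test --input trial.csv --mode full --alpha 0.05

# p-values; p' and the naive estimate are opt-in
permtest pvalue --input data.csv --w 999 --seed 7 --randomized

# type-I error of any configured test on synthetic null data
permtest simulate type1 --test randomized_random --n 8 --w 20 \
    --alpha 0.05 --reps 50000 --seed 1

# cautionary demonstrations
permtest demo phipson-smyth --w 10 --n 10 --reps 50000 --seed 1
permtest demo balanced --n 4 --reps 50000 --seed 1 --acknowledge-nongroup
```

Results are JSON with full provenance (seed record, scheme, `w`), enough to
replay any decision; warnings carry stable machine-readable codes.

## Layout

| module | contents |
| --- | --- |
| `permtest.transform_groups` | transformations, composition/inverse, group verification, orbits, random-draw schemes |
| `permtest.designs` | two-sample / sign-flip / rotation designs, statistic equivalence classes, representatives, balanced permutations |
| `permtest.perm_tests` | all test procedures |
| `permtest.pvalues` | all p-value constructions |
| `permtest.simulate` | synthetic data, the type-I error harness, demonstrations, claim registry |
| `permtest.cli_io` | CLI, CSV/TSV input, JSON output |
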