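# Methods

## Model

All quantities in this package are functionals of the degree-pair edge
partition of an undirected multigraph.  For a weight scheme φ — a symmetric,
strictly positive function of the two endpoint degrees — the index is
`I_φ = Σ_classes count·φ(d₁,d₂)`, the index polynomial is
`I_φ(x) = Σ_classes count·x^φ(d₁,d₂)` (whose derivative at x = 1 recovers
the index), and the entropy is the Shannon entropy of the normalised
edge-weight distribution `p_e = φ(e)/W`, `W = Σ φ`.  Because every built-in
weight depends only on endpoint degrees, the partition is a sufficient
statistic: the per-edge ("brute force") and per-class routes are
algebraically identical, and the package keeps both as mutually checking
implementations.

Graphs carry no element types, coordinates or bond orders; vertices are
opaque strings and parallel edges are allowed (self-loops never).  This is
deliberate: the descriptors are blind to everything but degrees, and the
configuration-model realizer below may need multi-edges.

## Structure families

The two built-in families are defined by their published edge-class count
polynomials, taken as the single source of truth:

* `NbO2(s,t)`: classes (2,3): 16, (3,3): 8(2s+2t−3), (3,4): 4(3st−2s−2t+2),
  (4,4): 2(2st−s−t); bond total 16st+6s+6t; atom classes
  {2: 8, 3: 4st+8s+8t−8, 4: 5st−3s−3t+2}, atom total 9st+5s+5t+2.
* `MOF(s,t)`: classes (1,3): 24st+1, (2,3): 6(s+t−1), (3,3): 2(28st−2s−2t+1),
  (3,4): 4(2st−s−t+1); bond total 2(44st−s−t)+1; atom total 74st (no
  per-valency split is published, so the vertex-side handshake is only
  certifiable for NbO2).

The domain is integer s, t ≥ 1: below it some class counts go negative,
which is meaningless, so the constructors raise.  At the domain corner
(1,1) a zero-count class may remain ((4,4) for NbO2); it is kept in the
stored partition and dropped only by explicit canonicalization, so that the
class structure of the family stays visible.

No explicit lattice adjacency is modelled for either family — the published
sources define them by figures plus the partitions, and every quantity in
scope needs only the partitions.  When a concrete graph is wanted (e.g. for
the per-edge oracle), `partition_to_graph` builds one.

## Closed forms and the discrepancy ledger

`closed_form(family, scheme)` expands `Σ count_poly(s,t)·φ(d₁,d₂)`
symbolically with exact coefficients (sympy), giving a bivariate polynomial
for the seven rational schemes and a surd combination for ABS.  The
verification suite checks, exactly, that these forms agree with the
partition sums at every integer point of the grid (s,t) ∈ {1..6}² (the test
suite extends this to {1..12}²).

The closed forms printed in the source for these families are stored
verbatim as fixtures and compared coefficient-by-coefficient.  Exact
arithmetic flags eight mismatches — constant-term errors (MOF B1: +14
derived vs +4 printed; MOF HB2: +531 vs +693; MOF ReZG3: +276 vs +384), a
spurious "+4" (MOF ReZG1: 74st vs 2(37st+2)), a wrong leading factor (NbO2
ReZG3: 16(95st−4s−4t−9) vs 8(…)), two closed forms printed in garbled
typography (both ReZG2 forms, read here as (4/7)(25st+11s+11t−27) and
(810/7)st−(198/35)(s+t)+198/35 respectively), and the ABS variant below.
In every decidable case the published *numeric* table sides with the form
derived from the partition, which is why the partitions are treated as
ground truth.

Three cells of the published NbO2 numeric table are themselves misprints
and are carried as documented errata rather than reproduced: HB2 at (4,4)
(408,872 for 40,872 — a misplaced thousands comma) and the ReG2 cells at
(5,5) and (10,10), whose printed digits differ from the exact rationals
27092/35 and 104292/35 beyond the printed precision.  The golden-table
comparison reports these cells with their corrected values and a WARN;
every other NbO2 cell reproduces at the printed precision.

### The ABS table variant

The standard atom-bond sum-connectivity weight on class (4,4) is
√(6/8) = √3/2 ≈ 0.866.  The published NbO2 ABS column is internally
consistent only under the weight √7/2 ≈ 1.323 on that class (the other
three classes carry the standard surds); with that variant set the column
reproduces to the printed six decimals.  The variant is implemented solely
as the explicitly named replication mode
(`abs_table_variant_value`, CLI `--abs-mode table_variant`) and is never
the default: the standard definition is the method, the table cell an
erratum to document.

## Entropy: numerical choices

Entropy is computed class-wise in log space,
`log W − (1/W)·Σ count·w·log w`, never by forming the products `Π w^w` that
appear in the rearranged textbook form — for HB2 weights up to 256 those
products overflow any float.  The logarithm base is a knob (natural by
default; 2 and 10 in the CLI) since every checkable property is
base-covariant: the value scales by 1/log b, the bound log m likewise.
Weights are required to be strictly positive and finite, so `w log w` is
always well defined; the ABS domain excludes the degree pair (1,1), whose
weight would be 0, and batch operations skip ABS with a warning when that
class is present rather than failing the whole report.  Verified tolerances:
rearranged vs direct −Σ p log p agreement and partition-vs-per-edge
agreement at 1e−10 absolute; bound and base-change identities at 1e−12.

## Fixture generators

`partition_to_graph` realizes a partition by a constrained configuration
model: the endpoint-slot count of each degree d must divide by d (otherwise
the partition is infeasible and a descriptive error is raised), fixing the
vertex set; each edge of class (d₁,d₂) then consumes one random free stub
on a degree-d₁ vertex and one on a distinct degree-d₂ vertex.  Degrees are
exact by construction, so any successful pairing round-trips the partition
exactly; the only stochastic failure is a forced self-loop, retried up to
1000 attempts per call (the partitions in scope are small and dense in
realizations, so in practice the first attempt succeeds).  Multi-edges are
accepted in the output — only degrees matter downstream.

`random_bounded_degree_graph(n, dmax, seed)` produces the seeded simple
graphs used by the oracle tests (default n = 60, dmax = 4, covering all
degree pairs the families use plus pairs they do not).  These generators
emulate nothing about real chemistry beyond bounded valency — they exist to
exercise the degree bookkeeping, so passing oracle tests certifies the
computational identities, not chemical realism of the fixtures; chemical
meaning enters only through the two family partition models.

## Design choices

* Exact rationals (`fractions.Fraction`) end to end for the seven rational
  schemes: table cells like 4772/35 must survive to the final rounding
  untouched by float error.  Display rounding is half-up to the printed
  number of decimals, with exact rationals retained in `*_exact` companion
  columns.
* Index-polynomial exponents are exact: `Fraction` keys for rational
  schemes (ReZG1 produces exponents like 7/12), exact sympy surds for ABS —
  classes are merged only when their exponents are exactly equal, never
  through float collision.
* The CLI (`compute`, `families`, `verify`) is a thin veneer; all logic
  lives in the library.  `verify` exits 0 iff all checks pass, with the
  eight known closed-form mismatches reported as expected errata (WARN),
  not failures.
* Problem sizes in the default verification run — grid {1..6}², 20 oracle
  fixtures of 60 vertices — keep the whole suite under a few seconds while
  covering every class polynomial's behaviour (the closed-form grid check
  is a polynomial identity certificate: agreement of a degree-(1,1)
  bivariate form on a 6×6 integer grid is overdetermined many times over).

## Limitations

* No explicit crystal lattices: results about the families are results
  about their published partitions.  If the partitions misdescribe the real
  structures, every downstream number inherits that.
* The entropy layer reports no published numeric values to compare against
  (none exist for these families); its correctness rests on the bound,
  equivalence and invariance properties.
* ABS values are floats (double precision); the exact-surd mode exists for
  verification, not for bulk tables.
* The MOL/SDF reader takes heavy-atom connectivity from the bond block of
  the first record only and ignores aromaticity perception entirely; it is
  a convenience entry point, not a general-purpose chemistry parser.
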