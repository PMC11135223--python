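# Methods

## Model and procedure

`snpmpc` computes set-operation cardinalities and the Jaccard similarity
between two genomes' SNP sets under secure multiparty computation. The
pipeline has three phases.

**Input phase.** Each data owner reduces a VCF to the set of tuples
(chromosome, position, reference allele, alternate allele), encodes it
against a public ordered panel of m variants as an m-bit presence vector,
and secret-shares the vector elementwise among the n computing parties.
Two sharing schemes are implemented:

* *Shamir threshold sharing*: the secret s ∈ Z_p is the constant term of a
  uniformly random polynomial of degree t; party i holds f(i). Any t+1
  shares determine s by Lagrange interpolation at 0; any t shares are
  jointly uniform. Default n = 3, t = 1 — the honest-majority,
  semihonest setting.
* *Additive sharing*: s is the sum of all n shares mod p; every proper
  subset is uniform. Works with as few as two parties, which suits the
  case where the two data owners themselves (plus no one else) compute.

**Computation phase.** Set operations are arithmetized elementwise over
Z_p (see README table). The only interactive primitive is multiplication
of two shared values, realized with Beaver triples: given a preprocessed
shared triple (a, b, c = ab), the parties open the masked differences
d = x − a and e = y − b — both uniform, hence harmless — and obtain shares
of xy = c + db + ea + de locally. One elementwise multiplication of
m-vectors consumes m triples and one communication round (the opens are
batched). Addition of shares, addition of a public constant, and scaling
by a public constant are local and cost nothing. The per-position result
vector is then summed locally — a free affine step — into a single shared
cardinality.

**Output phase.** Each party sends its share of the result only to the
querying user, who reconstructs. For Jaccard the user receives the
intersection and union sizes and divides in the clear, giving an exact
rational J ∈ [0, 1]. Division is *not* done inside MPC: a ratio is not a
native prime-field element, and opening the two integer sizes reveals
nothing beyond what J together with m already determines at the protocol's
granularity. (Secure fixed-point division would hide the sizes themselves;
it is out of scope here and noted as the alternative design.)

By default the union size inside the Jaccard protocol is derived from the
identity |A∪B| = |A| + |B| − |A∩B|, whose extra terms are local popcount
sums; this halves the triple cost from 2m to m. The direct elementwise
union protocol is kept for standalone use and as a cross-check (both
routes are asserted equal in the tests). Every protocol also has a
variant returning the shared result *vector* (skipping the final
summation); opening that vector reveals per-position membership and is
gated behind an explicit `reveal_positions=True`.

## Trust assumptions

* All parties are semihonest: they follow the protocol but may try to
  infer secrets from their view. Malicious security (verification,
  MAC checks, OT-based preprocessing) is out of scope.
* Beaver triples come from a **trusted dealer** — an explicit role that
  learns nothing about inputs but must produce correct, uniform triples.
  Production MPC frameworks replace the dealer with interactive
  preprocessing; the dealer is this runtime's declared substitution for
  that machinery.
* The panel is public and agreed beforehand; its content digest is carried
  by every encoded vector and sharing, and protocols refuse to combine
  vectors bound to different panels.
* Transports deliver messages reliably and in order per party pair. The
  in-process transport is deterministic and default; the localhost-TCP
  transport exercises the same protocol over real sockets. Wide-area
  deployment, TLS, and channel authentication are out of scope.

The test suite probes the semihonest guarantee empirically at small field
size: single Shamir shares of a fixed secret are chi-square-uniform over
10,000 sharings, and the distribution of messages a party receives during
the intersection protocol is statistically invariant to the other
provider's input.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `prime` | 2^61 − 1 | field modulus; must exceed the panel length m so cardinalities (≤ m) never wrap. The Mersenne prime far exceeds any realistic panel (10^6-SNP panels included) and keeps shares in 8-byte words. Primality is checked at construction. |
| `scheme` | `shamir` | `shamir` or `additive`. |
| `n_parties`, `threshold` | 3, 1 | honest-majority minimum for Shamir; additive admits n = 2. Shamir requires 1 ≤ t < n; evaluation points are party indices 1..n (never 0, where the secret lives). |
| `transport` | `inprocess` | or `tcp` (localhost mesh). |
| `seed` | `None` | `None` → OS CSPRNG (default posture). An integer seed is for tests and simulation only and is recorded in share-directory metadata. |
| `triple_budget` | 0 | triples dealt at session start; protocols raise `TripleExhaustedError` when the pool runs out — never a silent plaintext fallback. |

Encoding flags: `snps_only=True` (indels/MNVs excluded, with a counter;
the comparison model is SNP-presence), FILTER ignored by default
(`strict_filter` restricts to PASS/'.'), and presence is genotype-blind
(`require_alt_gt` optionally demands an alternate allele in GT). Matching
is exact on (Chr, Pos, Ref, Alt) with chromosome labels case-folded and
stripped of a leading `chr`; multi-allelic records contribute one key per
alternate allele.

## Synthetic data

The generator reproduces the *structure* of the tool's inputs, not human
population genetics:

* **Toy reference**: 2 chromosomes × 1 Mbp by default. The reference
  allele at a site is a deterministic hash of (chrom, pos), so all
  simulated individuals and panels agree on Ref — as real call sets
  against one reference build do. Desk-scale defaults (10^4 variants per
  individual, panels of 10^2–10^4) preserve the regime panel ≪ genome-wide
  variant count at seconds-to-minutes cost.
* **Individuals**: n uniform distinct positions, alternate allele uniform
  over the three non-reference bases; written as SNP-only VCF 4.2 that
  round-trips through the strict reader. For two independent individuals
  the shared-variant count is hypergeometric thinned by the 1/3
  same-alt probability; `expected_unrelated_overlap` gives the closed
  form, which the tests check observations against.
* **Trios**: each parental variant is inherited by the child
  independently with probability h (default 0.5, the Mendelian
  expectation for a heterozygous site), plus a de novo fraction (default
  0.001 of the per-parent variant count, a small nonzero rate). No
  linkage, recombination blocks, allele-frequency spectrum, or population
  structure — Jaccard-level kinship signal needs none of these, but
  absolute Jaccard values on real cohorts will differ (real parent–child
  pairs share long haplotypes and common variants are common), so passing
  tests demonstrate protocol exactness and relative separation, not
  calibrated real-data thresholds.
* **Panels**: either uniform positions on the reference (the analogue of
  a simulated genome-wide panel) or sampled from a cohort's observed
  variant universe (`panel_from_variants`), which emulates an informative
  published panel. The kinship evaluation uses the latter: on a 2-Mbp toy
  genome a uniform 2,000-SNP panel would hit only a handful of any
  individual's variants and drown the signal in small-count noise,
  whereas informative panels are precisely those chosen to segregate in
  the population of interest.

The evaluation pipeline (`panel_vs_whole_jaccard`, CLI
`evaluate similarity`) tabulates, for each pair, the whole-set Jaccard on
exact variant tuples and the panel-restricted Jaccard computed both in
plaintext and through the full secure pipeline, raising on any
disagreement — the secure path must be *exactly* the plaintext value,
since the protocols are exact over Z_p.

## Numerical and degenerate-input choices

* All arithmetic is exact big-integer arithmetic mod p; there is no
  floating point anywhere in the secure path. J is returned as an exact
  `Fraction`.
* m = 0 (empty panel) is legal: all cardinalities are 0 and J is
  undefined. An empty union likewise yields `jaccard = None` with a
  `defined` flag — never silently 0.
* Reconstruction fails loudly: every share record carries scheme, prime,
  threshold, party count and party index, and any mismatch (including
  panel-digest mismatch between vectors) raises instead of combining.
* Shamir reconstruction uses the first t+1 provided shares; any
  qualifying subset gives the identical answer (tested exhaustively for
  n = 5, t = 2).
* Cost accounting charges the serialized payload bytes actually
  transported (8 bytes per field element at the default prime) per
  directed party pair; a batched open is one round.

## Evaluation problem sizes

The shipped evaluation and acceptance runs use 50 trios of 10,000
variants per individual on the 2-Mbp toy reference with a 2,000-SNP
cohort-derived panel (200 scored pairs, each also run securely), 200
random vector pairs per scheme for oracle equivalence, 500 random Beaver
products in F_{2^61−1}, 10,000 sharings for the uniformity statistic, and
intersection runs at m ∈ {100, 1000, 10000} for the communication curve.
These sizes keep a full run in tens of seconds while leaving every
statistical margin wide.

## Known limitations

* Semihonest only; a malicious party can corrupt results undetected.
* The trusted dealer is a stronger assumption than interactive
  preprocessing; it is isolated behind `deal_triples` so a different
  preprocessing source can replace it.
* Presence-only comparison: zygosity and allele dosage are ignored (an
  optional GT flag filters records but does not change the set element).
* Threshold queries ("is J above x?") would require a secure comparison
  at the end of the protocol and are not implemented.
* The communication and time figures measured by the ledger characterize
  this runtime; they are not comparable to other MPC frameworks'
  published numbers.
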