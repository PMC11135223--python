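# snpmpc

Privacy-preserving comparison of genomic variant sets with secure
multiparty computation (MPC).

## The problem

Genomic variant data — typically a VCF listing a person's single
nucleotide polymorphisms (SNPs) — is both highly identifying and highly
useful: overlap between two variant sets reveals whether two samples come
from the same person or from close relatives. Hospitals, ancestry services
and researchers would like to run exactly such queries against each other's
data without ever exposing the underlying genomes.

`snpmpc` lets two data owners compare genomes so that

* no computing party learns either genome,
* only the querying user learns the result, and
* the result is exact, not approximate.

Each owner reduces a genome to its set of SNPs, identified by the tuple
(Chr, Pos, Ref, Alt). Both owners agree on a public, ordered panel of m
variants S and encode their sets A and B as m-bit presence vectors

    a_i = 1  iff the i-th panel variant is in A        (likewise b_i)

The bits are embedded in a prime field Z_p (p = 2^61 − 1 by default) and
secret-shared among n computing parties — Shamir threshold sharing
(default n = 3, t = 1) or additive sharing (n ≥ 2). On shares, each set
operation is elementwise arithmetic:

| operation           | arithmetization            | cardinality          |
|---------------------|----------------------------|----------------------|
| union               | c_i = a_i + b_i − a_i b_i  | Σ c_i = \|A ∪ B\|    |
| intersection        | c_i = a_i b_i              | Σ c_i = \|A ∩ B\|    |
| difference A\B      | c_i = a_i − a_i b_i        | Σ c_i = \|A \ B\|    |
| symmetric diff      | c_i = a_i + b_i − 2a_i b_i | Σ c_i = \|A Δ B\|    |

restricted to the panel. Multiplication of shares (π_mult) is interactive
and uses Beaver triples from a trusted dealer; additions and public-constant
operations are local and free. The final sum is opened only to the user,
who reconstructs the cardinality — and, for the Jaccard similarity
J = |A∩B| / |A∪B| ∈ [0, 1], receives the two sizes and divides in the
clear. J close to 1 indicates the same individual; parent–child pairs
sit near J ≈ 1/3 on an informative panel; unrelated pairs near 0.

The security model is semihonest (honest-but-curious) with honest-majority
Shamir or two-party additive sharing; preprocessing comes from an explicit
trusted dealer. See `docs/methods.md` for assumptions and limitations.

## Worked example

Simulate a family, build an informative 2,000-SNP panel, and compare the
child against both parents and the parents against each other — every
comparison running through encoding, secret sharing, Beaver multiplication
and user-side reconstruction:

```python
import random
from snpmpc import (ProtocolConfig, ToyReference, encode, panel_from_variants,
                    simulate_trio)
from snpmpc.protocols import secure_compare

rng = random.Random(11)
reference = ToyReference()                      # 2 chromosomes x 1 Mbp
father, mother, child = simulate_trio(reference, n_variants=10_000, rng=rng)

universe = father.variant_set | mother.variant_set | child.variant_set
panel = panel_from_variants(universe, 2_000, rng)

vec_child  = encode(panel, child.variant_set)
vec_father = encode(panel, father.variant_set)
vec_mother = encode(panel, mother.variant_set)

config = ProtocolConfig(scheme="shamir", n_parties=3, threshold=1, seed=42)
for name, vec in [("father", vec_father), ("mother", vec_mother)]:
    res = secure_compare(vec_child.bits, vec.bits, config, op="jaccard",
                         panel_digest=panel.digest)
    print(f"child vs {name}: |A∩B|={res.intersection_size} "
          f"|A∪B|={res.union_size} J={float(res.jaccard):.4f}")
```

prints

```
child vs father: |A∩B|=507 |A∪B|=1516 J=0.3344
child vs mother: |A∩B|=523 |A∪B|=1514 J=0.3454
```

(and `father vs mother` gives J=0.0000): the child shares about a third of
panel variants with each parent — the Mendelian expectation under
per-site inheritance with probability 1/2 — while the unrelated parents
share essentially none. The same comparison is available as a file-based
CLI workflow in which sharing, computing and reconstructing are separate
steps run by separate roles:

```sh
snpmpc simulate trio --out cohort --seed 2
snpmpc simulate panel --out panel.tsv --size 2000 --seed 1 --from-cohort cohort
snpmpc encode --vcf cohort/trio-father.vcf --panel panel.tsv --out father.pv
snpmpc encode --vcf cohort/trio-child.vcf  --panel panel.tsv --out child.pv
snpmpc share --vector father.pv --out-dir shares_f --seed 11
snpmpc share --vector child.pv  --out-dir shares_c --seed 12
snpmpc compute --op jaccard --shares-a shares_f --shares-b shares_c \
               --out-dir out --ledger ledger.json --seed 13
snpmpc reconstruct --op jaccard \
    --party-outputs out/party_1.out --party-outputs out/party_2.out \
    --party-outputs out/party_3.out
```

The last command prints `{"intersection": ..., "union": ...,
"jaccard": ..., "defined": true}`; `ledger.json` records the bytes
exchanged per party pair, the round count, and the number of secure
multiplications.

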