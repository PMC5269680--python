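# qword — ranking DNA words by spatial clustering

Functional DNA words — CpG dinucleotides, regulatory motifs, even
variable-length elements like exons — are not scattered uniformly along a
chromosome: like keywords in a text, they cluster. `qword` quantifies that
clustering and uses it to rank words by likely functional importance.

## The statistic

For a word *S* and a sequence scope, collect the start-to-start distances
*d* (in bp) between consecutive occurrences of *S* (overlapping and tandem
matches all count), and form the empirical survival curve

&nbsp;&nbsp;&nbsp;&nbsp;C(d) = P(D ≥ d).

If letters were independent with word probability ω (the product of letter
probabilities), distances would be geometric, C(d) = (1−ω)^{d−1} — an
exponential curve with characteristic distance x₀ = 1/|ln(1−ω)|.  Real
clustered words instead develop a power-law tail, captured by the
q-exponential (Tsallis) family

&nbsp;&nbsp;&nbsp;&nbsp;e_q(x) = [1 + (1−q)x]^{1/(1−q)},&nbsp;&nbsp;
C(d) ≈ e_q(−(d−1)/x₀),

which reduces to the exponential at q = 1 and decays as d^{−1/(q−1)} for
q > 1.  The fitted entropic index **q is the clustering score**: q ≈ 1
means random placement; larger q means stronger clustering.  Ranking all
words of a given length by q singles out the salient ones — on genomic
sequence, CG comes out on top, consistent with its role as the methylation
substrate.  A uniform shuffle of the sequence (composition preserved,
correlations destroyed) collapses any elevated q back to ~1, which is the
built-in null baseline.

## Worked example

Plant a clustered CG (q = 1.8, x₀ = 20 bp, 10,000 occurrences) into a
CG-sparse i.i.d. background and rank all 16 dinucleotides:

```python
import qword as qw

spec = qw.PlantSpec("CG", q_target=1.8, x0_target=20.0, n_occurrences=10_000,
                    background_probs={"A": 0.47, "C": 0.03, "G": 0.03, "T": 0.47},
                    seed=42)
planted = qw.planted_cluster_sequence(spec, mode="contaminated")
ranking = qw.rank_words([planted.record], qw.enumerate_kmers(2))
print(ranking.table.head(5))
```

```
word           scope      n     q    x0 r_squared    rms  converged status
  CG planted_CG_q1.8  10771 1.908  21.2    0.9996 0.0028       True     ok
  GC planted_CG_q1.8   2203 1.453 255.8    0.9950 0.0173       True     ok
  AA planted_CG_q1.8 187126 1.273   3.3    0.9969 0.0090       True     ok
  TT planted_CG_q1.8 187495 1.270   3.3    0.9969 0.0091       True     ok
  GG planted_CG_q1.8   1055 1.213 727.7    0.9958 0.0177       True     ok
```

The planted word is ranked first with q ≈ 1.9 (slightly above the target:
the background contributes extra CG occurrences and the discretisation
clamps the shortest distances).  GC inherits some clustering because every
adjacent "CGCG" contains one; the homodimers AA/TT sit at their usual
i.i.d. clump level q ≈ 1.27 (see `docs/methods.md`).  Shuffling kills it:

```python
shuffled = qw.shuffle_sequence(planted.record, seed=1)
fit = qw.fit_q_exponential(qw.empirical_ccdf(qw.word_distances(shuffled, "CG")))
print(f"shuffled CG q = {fit.q:.3f}")   # -> shuffled CG q = 1.000
```

The same chain is available from the shell:

```bash
qword simulate --plant-word CG --q 1.8 --x0 20 --n-occurrences 10000 --seed 42 --out planted.fa
qword rank --fasta planted.fa --k 2 --out ranking.tsv
qword shuffle --fasta planted.fa --seed 1 --out shuffled.fa
```

For fitting, `QExponentialFitter` / `ExponentialFitter` are scikit-learn
style estimators (`fit` on a raw distance sample, fitted attributes `q_`,
`x0_`, `r_squared_`, `rms_`, `converged_`, and `predict` for model CCDF
values), so they compose with sklearn tooling; `fit_q_exponential` /
`fit_exponential` are the equivalent one-shot functions.

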