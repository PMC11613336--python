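# fcmkit

Analysis toolkit for **fuzzy cognitive maps (FCM)** in participatory health
research. Stakeholder groups draw causal maps of an outcome they care about
— factors (nodes) linked by arrows whose signed weights express perceived
influence strength. `fcmkit` turns collections of such maps into comparable,
communicable analyses in four moments:

1. **Standardize** — harmonise factor labels across maps with a lexicon and
   juxtapose knowledge sources in pattern-correspondence tables.
2. **Closure** — compute the maximum influence of every factor on every
   other through all direct and indirect pathways (transitive closure), and
   quantify how much two knowledge sources disagree.
3. **Reduce** — group factors into categories and condense, aggregate or
   restrict the map into a communicable summary.
4. **Rank** — identify priority factors with post-closure network
   centralities (degree, weighted degree, betweenness), scaled to [0, 1].

## The model

A map is a directed graph on k factors. Weights are elicited as signed
integers in {−5..−1, 1..5} and scaled linearly to magnitudes in [0, 1]; an
unreported link has weight exactly 0. Storage is *bipolar*: each ordered
pair (i, j) carries a positive magnitude w⁺(i, j) and a negative magnitude
w⁻(i, j), so merged maps can hold conflicting signs.

A **walk** is a chain of links; its sign is the product of its link signs
(parity of negative links). Transitive closure assigns every pair two
values, TC⁺(i, j) and TC⁻(i, j), the strongest positive- and negative-sign
influence over all walks:

* **Fuzzy closure** — a walk is as strong as its weakest arrow:
  TC±(i, j) = max over walks of min link magnitude. Computed exactly by a
  max–min Floyd–Warshall pass over a parity-doubled graph (two copies of
  each node; positive links preserve parity, negative links flip it), with
  one witness walk recovered per pair and sign.
* **Probabilistic closure** — each link transmits independently with
  probability equal to its magnitude; TC±(i, j) is the probability that at
  least one transmitting path of that sign exists (two-terminal network
  reliability; exact by factoring, or Monte Carlo with standard errors).

The **net TC** is TC⁺ − TC⁻. Disagreement between two knowledge sources is
the average degree of disagreement

    d̄ = Σ|d| / N,

where |d| is the absolute difference of net-TC weights of the same link and
N counts the compared links (nonzero in at least one source). d̄ ranges from
0 to 2; d̄/2 normalises it to [0, 1]. A whole-map variant divides Σ|d| by
k², the cell count of the adjacency matrix.

## Worked example

The package bundles the net fuzzy-closure influences of 20 factors on unmet
postpartum care needs among recent immigrant women, as seen by three
knowledge sources (published literature, family physicians, birth
companions):

```python
from fcmkit import disagreement
from fcmkit.datasets import postpartum_net_influences

cols = postpartum_net_influences()
rep = disagreement(cols["Family Physicians"], cols["Birth Companions"])
print(rep.rounded(1), rep.n_compared)   # 0.3 20
rep = disagreement(cols["Family Physicians"], cols["Literature"])
print(rep.rounded(1), rep.n_compared)   # 0.4 14
rep = disagreement(cols["Birth Companions"], cols["Literature"])
print(rep.rounded(1), rep.n_compared)   # 0.4 18
```

Family physicians and birth companions disagree least (d̄ ≈ 0.3 over the 20
factors either group mentioned); each stakeholder group differs more from
the literature (d̄ ≈ 0.4). For a single factor the arithmetic is direct:
Caesarean section has influence 0.2 in the literature and 0.8 for birth
companions, so |d| = 0.6.

A closure example from scratch:

```python
from fcmkit import ConceptMap, fuzzy_closure, strongest_walks

m = ConceptMap()
m.add_link("A", "B", 0.6)    # A raises B
m.add_link("B", "C", -0.9)   # B lowers C
m.add_link("A", "C", -0.3)   # weak direct negative
res = fuzzy_closure(m)
print(res.tc_minus.loc["A", "C"])          # 0.6 (indirect walk beats direct link)
print(strongest_walks(res, pair=("A", "C"))[0].nodes)   # ('A', 'B', 'C')
```

The same pipeline is available from the shell:

```bash
fcmkit disagree --bundled postpartum --out report.csv
fcmkit closure --map mymap.csv --method fuzzy --out-prefix out/run1
fcmkit pipeline --map physicians a.csv --map companions b.csv \
    --outcome "Unmet postpartum care needs" --out-dir out/
```

Every command writes a `.provenance.json` record (inputs, parameters, seed,
version) beside its outputs.

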