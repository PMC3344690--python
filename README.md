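# fdiversity

Terminology diversity of categorized attributes in medical report
collections.

Narrative (free-text) medical reports describe the same clinical attribute —
smoking status, allergy, dyspnoea — with many different surface terms, while
structured reports code it with a fixed category set. `fdiversity`
quantifies that difference: it measures how unpredictable the recorded
categories of an attribute are, compares two report collections
statistically, folds narrative surface terms onto canonical categories, and
generates synthetic paired collections with known ground truth for
validation. It is aimed at medical informatics and biostatistics users
working with categorized EHR data in any language.

## The measures

For an attribute with categories `A_1..A_k` and probabilities
`p = (p_1, ..., p_k)`, the package implements the f-diversity family: given
a convex generator `f` with `f(1) = 0`, the f-entropy is

    H_f(p) = Σ_i p_i² f(1/p_i) + f(0) Σ_i p_i (1 − p_i),

the `p`-weighted average of the per-category self diversities
`R_{f,i}(p) = p_i f(1/p_i) + f(0)(1 − p_i)`. Built-in generators give the
classical indices:

| generator | f(t) | H_f(p) | rarity R_i |
|---|---|---|---|
| `gini_simpson` | `t − 1` for `t > 1`, else 0 | `1 − Σ p_i²` | `1 − p_i` |
| `shannon` | `t log t` | `−Σ p_i log p_i` | `−log p_i` |
| `number_of_categories` | `(t − 1)²` | `k − 1` | `(1 − p_i)/p_i` |
| `order_beta(β)` | `(t − t^(1−β))/β` | order-β index | `(1 − p_i^β)/β` |

Relative versions divide by the value at the uniform distribution, mapping
every attribute onto `[0, 1]`; the marginal diversity of a category is the
f-diversity of the dichotomy `(p_i, 1 − p_i)`, normalized by its value at
`(1/2, 1/2)`. Diversities are estimated by plugging in empirical
frequencies over recorded (non-missing) reports, and two collections are
compared with `Z = (Ĥ_a − Ĥ_b) / √(V_a + V_b)` where
`V = (4/n)(Σ p̂_i³ − (Σ p̂_i²)²)` is the large-sample variance of the
Gini-Simpson estimate.

## Worked example

The package ships the category counts of a study of 110 Czech narrative and
1119 structured cardiology reports over eight attributes of the Minimal Data
Model for Cardiology (MDMC):

```python
from fdiversity import load_fixture, compare_gini_simpson

fx = load_fixture()
r = compare_gini_simpson(fx.narrative["Smoking"], fx.structured["Smoking"])
print(round(r.estimate_a.relative_estimate, 4))   # 0.8162
print(round(r.estimate_b.relative_estimate, 4))   # 0.6579
print(round(r.z, 2), r.p_value_text, r.significant)  # 3.25 0.00115 True
```

The narrative collection records smoking status far less predictably
(relative Gini-Simpson diversity 0.8162 of its maximum) than the structured
one (0.6579), and the difference is significant at the 5% level
(Z = 3.25). Running the comparison over all eight attributes,

```sh
fdiversity compare --fixture
```

flags every attribute significant except Allergy (p = 0.25468) — structured
recording is systematically less diverse. `fdiversity summarize --fixture
--out-dir tables/` writes the full per-attribute and per-category diversity
tables, and `fdiversity simulate --seed 1 --out-dir sim/` generates a
synthetic paired collection set (surface-term noise: dropped diacritics,
abbreviations, typos, case drift) with a complete truth record.

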