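# netprio

Network-based prioritization of pull-down interactome proteins.

Affinity pull-down followed by LC-MS/MS yields hundreds of putative binding
partners for a bait protein; most are background or weak interactors. This
package implements the full prioritization chain used to nominate follow-up
candidates from such a list — here, the membrane interactome of a trimeric
surfactant protein D fragment in PC3 prostate cancer cells, from which
GRP78/HSPA5 emerges as the top candidate:

1. **Evidence filter** — keep proteins identified with ≥2 unique peptides and
   ≥2 peptide-spectrum matches (PSMs); add the bait back explicitly.
2. **Network construction** — read a STRING-style edge list
   (`protein1 protein2 combined_score`, score 0–1000), drop edges below a
   confidence cutoff (default 0.4, STRING "medium"), and induce the
   subnetwork on the filtered protein set.
3. **Node scoring** — three analyses per node *v* of the unweighted graph
   *G*:
   - *hub*: degree *k(v)*;
   - *perturbation*: *P(v) = |C(G) − C(G∖v)|*, where the network centrality
     index *C(G)* is the mean over nodes of (clustering coefficient +
     pair-normalized betweenness + normalized harmonic closeness)/3;
   - *disruption*: *D(v)* = mean increase in shortest-path length
     *d(u,w)* over pairs connected in *G* (pairs severed by the deletion are
     penalized at *|V| − d_G(u,w)*, and their count is reported).
4. **Rank aggregation** — dense ("1223") ranks per analysis, averaged
   exactly (ties compared on integer rank sums, 2-decimal display), then
   dense-ranked again into the cumulative rank; the top 5 % is shortlisted
   without ever splitting a tie class.
5. **Annotation screen** — shortlisted proteins are checked against boolean
   annotation tables (tissue expression, disease association, metastasis,
   apoptosis); final candidates satisfy a configurable conjunction.
   Annotations are three-valued: absent entries are *unannotated*, never
   silently false.

A synthetic-data module generates seeded stand-ins for all three inputs
(heavy-tailed interaction networks with an optional planted hub, evidence
tables with a controlled pass fraction, annotation tables with stated
prevalences), and the published 20-protein rank and annotation tables are
embedded as fixtures.

## Worked example

```python
from netprio import aggregate_ranks, screen_candidates, table1_fixture, table2_fixture

hub, pert, disr, _ = table1_fixture()        # the published 3×20 per-metric ranks
table = aggregate_ranks(hub, pert, disr)
print(table.head(4))

shortlist = list(table.index)
report = screen_candidates(
    shortlist,
    table2_fixture(),
    ["prostate_cancer_metastasis", "prostate_expression"],
    cumulative_ranks=table["cumulative_rank"].to_dict(),
)
print(report.criterion_counts)
print(report.final_candidates)
```

prints

```
          hub_rank  perturbation_rank  ...  average_rank  cumulative_rank
protein                                ...
GAPDH            1                  1  ...          1.00                1
HSPA8            2                  2  ...          2.33                2
HSP90AA1         3                  3  ...          6.33                3
HSPA4            4                  6  ...          6.33                3

[4 rows x 5 columns]
{'prostate_expression': 16, 'prostate_cancer': 15, 'prostate_cancer_metastasis': 2, 'apoptosis': 15}
['HSPA5']
```

GAPDH ranks first under all three analyses (average 1.00, cumulative 1);
HSP90AA1 and HSPA4 tie at average 6.33 and share cumulative rank 3. Of the
20 shortlisted proteins, 15 are associated with prostate cancer and exactly
two (HSP90AA1, HSPA5) with prostate cancer metastasis; requiring prostate
glandular expression as well leaves HSPA5 (GRP78) as the sole candidate.

The same chain runs from the shell on files:

```sh
netprio simulate --seed 11 --n 200 --planted-hub 0.5 --pass-fraction 0.9 --out-dir sim
netprio run sim/identifications.tsv sim/edges.tsv sim/annotations.tsv --output-dir out
```

which filters the identifications, builds the induced network, writes the
score and rank tables plus a candidate report and a run manifest, and prints
the per-criterion counts over the shortlist.

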