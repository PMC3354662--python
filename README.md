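# fluxrank

Disease-gene prioritization on coexpression-weighted protein-interaction
networks. Given an undirected protein-interaction network (PIN), a
control/case expression matrix, and a set of seed genes with validated
disease association, `fluxrank` ranks every candidate gene by its estimated
disease relevance. It is aimed at systems-biology practitioners who have a
disease-specific microarray (or comparable expression-summarized) dataset
and want a ranked candidate list to guide validation.

## Method

The pipeline combines a *global* diffusion filter with a *local*
shortest-path score:

1. **Edge-flux filter.** For each condition c ∈ {control, case}, edge
   weights are the Pearson correlations of the endpoint genes over that
   condition's samples. A row-stochastic matrix
   S<sub>ij</sub> = |w(i,j)| / Σ<sub>k</sub> |w(i,k)| drives a random walk
   with restart (restart probability γ = 0.3, restarting uniformly on the
   seed genes), giving stationary probabilities r. The flux on a directed
   edge is ef<sub>ij</sub> = r<sub>i</sub> S<sub>ij</sub>, and the per-edge
   statistic is EF = log₂(ef<sup>case</sup> / ef<sup>control</sup>).
   Edges in the two tails of the EF distribution (normal fit, per-tail
   fraction t ∈ {0.025, 0.05, 0.10} by default) form one filtered
   subnetwork per threshold.
2. **Distance weighting.** Per gene, the differential-expression value is
   EV = |mean(control) − mean(case)|; min–max normalized and passed through
   −ln(·) it becomes a distance (strongly differential genes ≈ 0). An edge's
   distance is the sum of its endpoints' transformed values, so paths through
   differential genes are short.
3. **Seed-path scoring.** On each filtered subnetwork, all shortest paths
   between all gene pairs are enumerated; paths containing at least one seed
   enter the scoring list. With denom = Σ 1/lᵢ over stored paths, a gene
   scores Σ<sub>paths∋gene</sub> (1/lⱼ) / denom ∈ [0, 1]. Each score is then
   multiplied by (2 − cc), where cc is the gene's local clustering
   coefficient — sparsely interconnected hubs ("broker" genes) are boosted.
4. **Borda vote.** Each subnetwork ranks its genes; position j earns weight
   1/j, and a gene's voting score is the sum of its weights across
   subnetworks.
5. **Expression boost.** Final score = voting score × (1 + normalized ADE),
   where ADE is the min–max-normalized EV. Genes are ranked by final score.

A packaged seed list of 15 prostate-cancer genes (OMIM-derived) ships with
the package; a synthetic generator produces desk-scale networks with a
planted, differentially expressed, case-coexpressed disease module for
testing and benchmarking without any downloads.

## Worked example

```sh
fluxrank make-fixture --out-dir demo --n-genes 120 --module-size 12 \
    --n-seeds 4 --n-control 10 --n-case 12 --rng-seed 7
fluxrank run --network demo/network.tsv --expression demo/expression.tsv \
    --groups demo/groups.tsv --seeds demo/seeds.txt --output demo/ranking.tsv
head -6 demo/ranking.tsv
```

```
rank    gene    voting_score    normalized_ade  final_score
1       G0026   2.5             0.833512126521  4.5837803163
2       G0007   1.66666666667   0.621833636997  2.70305606166
3       G0065   0.95            0.634735620357  1.55299883934
4       G0069   0.75            1               1.5
5       G0036   0.75            0.798793334823  1.34909500112
```

`voting_score` is the Borda sum across the three threshold networks (here
bounded by 3; G0026 was ranked highly in all of them), `normalized_ade` the
gene's differential-expression boost in [0, 1], and `final_score` their
product via the (1 + ADE) factor. Evaluating against the planted module:

```sh
fluxrank evaluate --ranking demo/ranking.tsv --targets demo/truth.txt --ks 10,20,50
```

```
 k  count  precision   recall  average_position
10      7       0.70 0.583333          4.142857
20      8       0.40 0.666667          5.625000
50      8       0.16 0.666667          5.625000
```

Seven of the twelve planted module genes land in the top 10 of 120
candidates (random expectation: one), with the found targets sitting at
mean rank 4.1.

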