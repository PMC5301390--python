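# Optional walkthrough: a hard tetrapod 18S rRNA tree posterior (DS1)

The tetrapod 18S ribosomal RNA alignment known as **DS1** (Hedges and
colleagues' 27-taxon dataset) is a classic stress test for phylogenetic
MCMC: its tree posterior is bimodal, so a single chain tends to shuttle
between two clusters of topologies and two independent chains can appear
to sample different distributions. None of that data ships with this
package — the traces are large and are produced by running a sampler
(e.g. JPrIME or MrBayes) yourself — but if you have two trace files from
independent runs on DS1-like data, the whole published analysis can be
reproduced from the command line.

## What you need

Two tab-separated trace files (`trace1.p`, `trace2.p`), each with an
iteration column, at least one numeric posterior column, and a Newick
tree column. Roughly 10^5 samples per chain is typical.

## Single-chain analysis

```sh
phylotrace analyze trace1.p --burnin auto --json report1.json
```

The report contains, per numeric parameter, the summary statistics,
ESS, Geweke z, PSRF and the suggested burn-in; and for the tree column
the posterior topology table (sorted by probability) plus the weighted
majority-rule consensus. For a bimodal posterior expect the consensus
to contain a handful of low-support edges where the top topologies
disagree — on DS1 the consensus of the five most probable trees shows
five edges with support below 1.0.

To look at tree space, use the library directly:

```python
from phylotrace import parse_trace, topology_frequencies, rf_matrix, mds_2d

table = parse_trace("trace1.p")
post = topology_frequencies(table.tree_data["tree"], burnin=25_000)
dm = rf_matrix(post)            # topologies with posterior >= 0.2%
emb = mds_2d(dm)                # 2-D classical MDS embedding
```

On a bimodal posterior the embedding separates into two clusters whose
point sizes (posterior probabilities) are dominated by the two modal
topologies, with satellite topologies around each mode. Use
`mark_occurrences` on the top topologies to colour the trace: frequent
alternation between modes indicates the chain is at least transitioning;
long single-colour stretches indicate the tree parameter is stuck.

## Two-chain comparison

```sh
phylotrace compare trace1.p trace2.p --burnin1 0.25 --burnin2 0.25 --json cmp.json
```

For DS1-like data expect the Mann-Whitney U test to reject for at least
one numeric parameter and the split chi-square test to reject on the
tree column — the signature of two chains sampling different parts of a
multimodal posterior (or of incomplete convergence).

## A synthetic stand-in

The test suite runs this pipeline end-to-end on a small synthetic
bimodal posterior (two topology clusters generated by
`phylotrace.simulate`); see
`tests/test_acceptance.py::test_bimodal_walkthrough_is_documented_and_runs`.
That exercises the mechanics, not the biology: conclusions about the
real dataset require the real traces.
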