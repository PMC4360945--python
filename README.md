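# screenfunnel

A tested, reusable implementation of a structure-based virtual-screening
funnel: staged docking-score filters, a cross-program pose-consistency
filter based on symmetry-corrected in-place RMSD, and a top-decile binary
consensus vote over multiple scoring criteria. A synthetic library
generator stands in for commercial docking engines, so every stage is
testable offline.

## Pipeline

1. **Score threshold stages** — keep compounds whose raw score on a
   criterion satisfies a comparator (default: strict `< 5.0` on the first
   docking score, strict `< 3.0` on the redocking score).
2. **Pose-consistency stage** — for each compound with a pose from both
   programs, compute the symmetry-corrected *in-place* heavy-atom RMSD
   (no superposition; both poses share the receptor frame; minimised over
   the molecular graph's automorphism group) and keep pairs with
   RMSD strictly below 2.0 Å.
3. **Consensus vote** — rank compounds per criterion (competition
   ranking, rank 1 = most favourable), flag top-10% membership per
   criterion, sum binary votes (max 5 with the default five criteria:
   two docking scores, a rescoring value, a predicted pKi, and the pose
   RMSD), and select a 5,000-compound shortlist. Ties break by ascending
   mean normalized rank, then compound id.

## Modules

| module | purpose |
|---|---|
| `screenfunnel.score_io` | CSV score tables, multi-record SDF V2000 poses (heavy atoms only, SD-tag scores), hit-list CSV round-trip |
| `screenfunnel.pose_rmsd` | graph isomorphism / automorphism enumeration, in-place and Kabsch RMSD, pose-consistency test |
| `screenfunnel.consensus_vote` | per-criterion ranks, top-fraction membership, cumulative votes, shortlist selection |
| `screenfunnel.funnel` | stage orchestration, per-stage survivor/drop reporting, YAML config |
| `screenfunnel.synthetic_screen` | correlated criterion scores with planted binders; pose pairs with jitter, automorphism relabelling and gross displacement |

## CLI

```sh
# generate a synthetic library
screenfunnel synth make --config synth.yml --out-dir lib/

# pairwise pose-consistency RMSD between two SDF files
screenfunnel rmsd lib/poses_a.sdf lib/poses_b.sdf --cutoff 2.0 --out rmsd.csv

# consensus vote over a score table
screenfunnel vote --scores lib/scores.csv --config vote.yml --out hits.csv

# full funnel
screenfunnel funnel run --config funnel.yml --scores lib/scores.csv \
    --poses-a lib/poses_a.sdf --poses-b lib/poses_b.sdf \
    --out hits.csv --report report.json
```

Configs are YAML with `schema_version: 1`; see
`tests/test_funnel.py::TestConfigAndCli` for complete examples.

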