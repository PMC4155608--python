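# famtrend

Non-interactive toolkit for exploring a protein-family multiple sequence
alignment (MSA): pixel-per-residue **trend images**, sequence-similarity
**sorting weights**, per-column **consensus/conservation statistics**,
**parent-vs-mutant diffing** with candidate functional-mutation
shortlists (consensus-restoring positions, symmetric position pairs),
and optional mapping of alignment columns onto a 3D structure chain with
distances to a user-supplied residue site.

## Library overview

| module | contents |
| --- | --- |
| `famtrend.sequence_io` | aligned FASTA / FASTA / PDB readers, `AlignedFamily`, terminal-filler detection |
| `famtrend.residue_schemes` | chemical / polarity / charge / solvent-contact partitions, frequency bins, palettes, legends |
| `famtrend.similarity` | edit distance, class-weighted edit distance, positional/compositional common residues, shared n-grams, selected-column edit distance, fragment-frequency weight, `sort_family` |
| `famtrend.family_stats` | per-column distributions, consensus, reference match profile, conserved columns |
| `famtrend.mutation_finder` | `diff_runs` (maximal differing-column runs), `consensus_candidates`, `symmetric_pairs`, report export |
| `famtrend.trend_raster` | deterministic PNG rendering of the family (one pixel block per residue), paddle overlays |
| `famtrend.structure_map` | semiglobal column-to-residue mapping, heavy-atom site proximity, selection strings |
| `famtrend.fixtures` | seeded synthetic families with planted consensus, candidates and symmetric pairs |

Conventions: alignment columns are 1-based in every user-facing output;
`'X'` is accepted as an unknown residue but never matches anything in
similarity metrics; internal gaps (`-`, rendered white) are distinct
from terminal filler (rendered gray).

## CLI

```sh
famtrend fixtures --n-rows 200 --length 250 --rate 0.05 \
    --candidate 10:K:D --offset 22 --seed 17 --out fix/

famtrend sort --alignment fix/family.fasta --reference parent \
    --metric weighted_edit --scheme polarity --out sort.tsv

famtrend render --alignment fix/family.fasta --reference parent \
    --scheme charge --window 20:30 --out trend.png   # + legend/order TSVs

famtrend consensus    --alignment fix/family.fasta --out consensus.fasta
famtrend distribution --alignment fix/family.fasta --columns 10,22 --out dist.tsv
famtrend diff         --alignment fix/family.fasta --ref parent --alt mutant --out runs.tsv
famtrend candidates   --alignment fix/family.fasta --parent parent --mutant mutant --out report.tsv
famtrend symmetric    --alignment fix/family.fasta --parent parent --mutant mutant --out pairs.tsv
famtrend map          --alignment fix/family.fasta --reference parent \
    --pdb model.pdb --chain A --out map.tsv
famtrend near-site    --pdb model.pdb --chain A --candidates 107,138 \
    --site 95,165 --cutoff 8 --out prox.tsv
```

Exit codes: 0 success, 1 data error, 2 usage error.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
comparisons, planted-truth recovery, raster determinism), each with its
own runtime budget; the remaining files are unit and property tests
(hypothesis) per module, with independent brute-force oracles in
`tests/oracles.py`.

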