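# corralign

Correlation-map-guided global protein sequence alignment.

`corralign` aligns pairs of protein sequences with a dynamic program whose
substitution score combines a conventional 20×20 matrix with a 400×400
residue-*pair* substitution matrix evaluated at correlated position pairs.
The correlated pairs come from a per-sequence position×position correlation
map (supplied externally, e.g. by a protein language model, or synthesized),
and for each correlated partner the aligner probes a sliding window of
candidate positions in the second sequence and takes the best pair score.

The package also provides:

- **Matrix builders** (`corralign.coevo_build`): construct the 20×20 and
  400×400 log-odds tables from MSAs using mutual information or mean-field
  direct coupling analysis (DI) to rank column pairs, with the top 15% of
  pairs (by default) forming the foreground counts.
- **Embedding signatures** (`corralign.embedsig`): compress per-residue
  embedding matrices to fixed 5×44 and 3×85 blocks via orthonormal 2D-DCT
  truncation, compare them by L1 distance, and gate alignment parameters
  (correlation cutoff, pair-matrix weight `w2`) by homolog closeness.
- **Structure evaluation** (`corralign.struct_eval`): Kabsch superposition
  and an alignment-quality metric defined as the superposed RMSD over
  matched columns divided by the number of matched residues.
- **Synthetic generators** (`corralign.synthgen`): deterministic MSAs with
  planted covarying column pairs, ideal-geometry Cα toy structures, random
  correlation maps and embeddings — everything the test surface needs, with
  no downloads.

## Quick start (library)

```python
import corralign as ca

a = ca.ProteinSequence(id="a", residues="MKVLITDEWAKRHG")
b = ca.ProteinSequence(id="b", residues="MKVITDEWSKRHG")
m20 = ca.load_named_matrix20("blosum62")
params = ca.DPParams(w1=1.0, w2=0.0, gap_open=10, gap_extend=0.5)
result = ca.align_global(a, b, m20, params)
print(ca.write_alignment(result, a, b, format="pair", m20=m20))
```

To use pair scoring, load a correlation map and a 400×400 matrix and pass a
`PairBonusContext`:

```python
cmap = ca.load_corrmap("corr.txt", expected_n=len(a)).rescaled()
pairs = ca.select_pairs(cmap, cutoff=0.5, min_separation=3)
m400 = ca.parse_matrix400(open("ps400.txt").read())
ctx = ca.PairBonusContext(pairs=pairs, matrix400=m400, window=10)
result = ca.align_global(a, b, m20, ca.DPParams(w2=0.1), ctx)
```

## Command line

A single entry point `corralign` exposes all operations:

```sh
corralign align a.fa b.fa --matrix20 blosum62 --w2 0            # plain Gotoh
corralign align a.fa b.fa --corr corr.txt --matrix400 ps400.txt # pair-guided
corralign build-ps400 --msa-dir msas/ --method mfdca --out ps400.txt
corralign build-protsub --msa-dir msas/ --out protsub.txt
corralign embed-distance --layer26 eA26.txt eB26.txt --layer14 eA14.txt eB14.txt
corralign gate --distance 12000
corralign contact-map --pdb model.pdb --out contacts.txt
corralign eval-rmsd --alignment aln.fa --pdb-a a.pdb --pdb-b b.pdb
corralign synth msa --depth 100 --width 30 --planted 3:12 --seed 1 --out fam.afa
```

Exit code 2 signals an input/usage problem; 1 an internal failure.

### File formats

- Sequences/MSAs: FASTA and aligned FASTA; Stockholm (read-only).
- 20×20 matrices: NCBI/EMBOSS text dialect (BLOSUM62 and PAM250 bundled).
- 400×400 matrices: TSV of `<XY> <ZW> <score>` lines, `#` comments, optional
  `default=<real>` header; the (i,j,k,l)↔(j,i,l,k) identity is enforced.
- Correlation maps: dense whitespace matrix or 1-based sparse `i j value`
  triplets.
- Structures: single-chain PDB (Cα).

## Testing

```sh
python -m pytest -q tests/
```

The suite includes per-module unit tests, hypothesis property tests, and
`tests/test_acceptance.py`, which checks the aligner against exhaustive
alignment enumeration, the DCT compression against an explicit cosine-basis
oracle, Kabsch against a quaternion-method oracle, the DCA builder against
planted-coupling simulations, and end-to-end byte determinism.

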