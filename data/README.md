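# data

Optional user-supplied inputs.

- `mut16_O62011.fasta` — the MUT-16 scaffold sequence (UniProt O62011),
  used by the sequence-composition checks and reported by
  `scripts/acceptance.py` when present. Not bundled; download it from
  UniProt and place it here:

      curl -o data/mut16_O62011.fasta https://rest.uniprot.org/uniprotkb/O62011.fasta
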