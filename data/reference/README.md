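# Reference sequences

Place UniProt FASTA records here to run the accession-gated analyses
offline:

* `C7H4X2.fasta` — MAM, full-length (135 aa)
* `C7H4X1.fasta` — PCAT, the cognate ABC transporter

Fetch them with network access via:

```bash
mampipe fetch-uniprot --accession C7H4X2 --out data/reference/C7H4X2.fasta
mampipe fetch-uniprot --accession C7H4X1 --out data/reference/C7H4X1.fasta
```

`mampipe.io_formats.load_reference_protein` looks in this directory before
attempting any network fetch.
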