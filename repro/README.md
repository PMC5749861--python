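# Full corpus protocol

The package's tests and acceptance script run on synthetic data. The
published corpus-scale evaluation additionally needs three external
inputs that cannot be redistributed here:

1. **Known associations** — the HMDD v2.0 set of 5430 experimentally
   supported miRNA–disease pairs (495 miRNAs × 383 diseases), as a
   two-column TSV `(miRNA, disease)`.
2. **miRNA functional similarity** — the curated matrix distributed as
   `misim.zip` (cuilab.cn), converted to a labeled TSV grid with empty
   cells for undefined pairs.
3. **Disease DAGs** — MeSH descriptor ancestry for the 383 diseases,
   flattened to a three-column TSV `(disease, child_term, parent_term)`
   with `-` as the parent for declared roots. Any MeSH parser can produce
   this; the package deliberately does not parse MeSH itself.

Names must match the association file exactly; unmatched names fall back
to the interaction-profile kernel and are logged.

With those files in place, `full_protocol.py` runs global LOOCV (5430
refits), local LOOCV, and 100 repeats of 5-fold cross-validation. Expect
hours to days on a single CPU: each round refits both perspectives from
the masked matrix. Subsampled smoke runs are available via `--budget`.
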