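# External data drop-in

The source study's supplementary genotype tables are not redistributable
with this package.  To enable the supplementary-data checks in
`tests/test_acceptance.py`, export them as tab-delimited long tables with
columns `sample_id  population  locus  run_id  allele_a  allele_b`
(missing calls as `.`) and place them here as:

- `microsatellite_genotypes.tsv` - ancient microsatellite genotypes
  (loci Cha113, Cpa103, Cpa4; allele labels are fragment sizes in bp)
- `snp_genotypes.tsv` - ancient and modern SNP genotypes
  (populations `ancient` and `modern`)
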