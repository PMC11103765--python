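# File formats

All outputs are plain-text CSV with a `#`-prefixed provenance header
(tool version, parameters, seed). All readers skip `#` comment lines.

## Genotype matrix CSV
One row per individual (`individual` index column), one column per
locus. Cells are either text codes `hom1`/`het`/`hom2` with `NA`
(missing) and `NC` (dead-zone no-call), or the numeric export: allele-2
dosage `0`/`1`/`2` with `NA`. VCF input is also accepted (biallelic SNP
records, `GT` field, `./.` missing; REF = allele 1).

## Population map CSV
`individual,population[,sample_type]` — sample types are
`hair`/`swab`/`tissue`.

## Locus table CSV
`locus_id,scaffold,position,allele1,allele2,probe1,probe2,flank,class_label`
— positions 1-based; probes are the allele-specific sequences counted in
reads; `class_label` is `neutral` or `adaptive`.

## Primer CSV
`locus_id,fwd,rev[,concentration_nM]` — sequences 5'→3' over ACGT.

## Performance CSV (mix formulation)
`locus_id,on_target_share`.

## Counts CSV (genotyper output)
`individual,locus_id,n1,n2,total_reads,on_target_reads`.

## Reads
Single-end FASTQ, one file per individual, plain or gzipped; qualities
are read but ignored. Amplicon references are written as FASTA.
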