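# Shared configuration for the numbered analysis drivers.
# A 10-family x 2-tank x 20-fish design with 2,000 SNPs: large enough for
# stable variance components, small enough to run in minutes on one CPU.
simulate:
  n_families: 10
  n_fish_per_tank: 20
  n_snps: 2000
  seed: 2024
grm:
  maf_min: 0.01
  call_rate_min: 0.9
fit:
  pairs:
    - {trait1: fcr, trait2: mean_rg, level: tank}
    - {trait1: fcr, trait2: mean_alc, level: tank}
    - {trait1: fi, trait2: mean_wg, level: tank}
    - {trait1: wg, trait2: atom_amn, level: individual}
regress:
  candidates: [fi, mean_rg, mean_amc, mean_amn, mean_alc, mean_aln, mean_aac]
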