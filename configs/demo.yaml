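# Demo pipeline: a compact SSD RIL study that runs in about a minute.
seed: 11
out_dir: rilmap_demo
simulate: true
n_lines: 80
selfing_generations: 9
genotyping_error_rate: 0.01
missing_rate: 0.05
n_chromosomes: 6
chrom_length_bp: 5000000
chrom_morgans: 1.0
snp_density: 200
window_size: 15
min_match: 9
min_bin_length: 250000
threshold_method: bonferroni
alpha: 0.05
merge_gap: 2000000
run_bsa: false
run_coexpr: true
k_clusters: 4
d_prime_threshold: 0.8
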