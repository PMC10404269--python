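# Column-name library for heterogeneous GWAS summary-statistics headers.
# Each canonical field maps to an ordered list of accepted aliases
# (matched case-insensitively after stripping '#'). Alias lists must be
# disjoint across canonical fields.
rsid: [rsid, snp, snpid, markername, variant_id, id, marker, rs_id]
chr: [chr, chrom, chromosome, chr_id]
pos: [pos, bp, position, base_pair_location, pos_b37, bp_hg19]
a1: [a1, effect_allele, allele1, ea, alt, testedallele]
a0: [a2, a0, other_allele, allele2, nea, ref, reference_allele, noneffect_allele]
beta: [beta, b, effect, log_odds, beta_hat, effect_size]
odds_ratio: [or, odds_ratio, oddsratio, or_fixed]
z: [z, zscore, z_score, zstat]
se: [se, stderr, standard_error, se_beta, sebeta, std_err]
freq: [freq, eaf, af, maf, effect_allele_frequency, freq1, af1, frq]
n: [n, n_total, sample_size, neff, n_eff, totaln]
n_cases: [n_cases, ncase, n_cas, ncases, cases]
n_controls: [n_controls, ncontrol, n_con, ncontrols, controls]
pval: [p, pval, p_value, pvalue, p_bolt_lmm]
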