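# Example end-to-end scenario for `finmix run`.
seed: 7
out_dir: finmix_run
n_per_source: 50
mixture_n: 150
survey_years: [2014, 2015, 2016, 2017, 2018, 2019, 2020, 2021]
trade_years: [2014, 2015, 2016, 2017, 2018, 2019, 2020, 2021, 2022]
focal_species: "Carcharhinus longimanus"
focal_probability: 0.007
msa_iters: 20000
msa_burn_in: 10000
msa_chains: 4
structure_permutations: 999
trend_alpha: 0.05
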