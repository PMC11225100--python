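# Canonical study configuration: the two inflammatory-protein chains
# (IL-6: a=.274, b=.125; CRP: a=.429, b=.108; no direct path) crossed with
# sample sizes 100/250/500, 1000 replications each, unit residual variances.
seed: 20230629
variance_convention: unit_residual
alpha: 0.05
ref_method: unadjusted
scenarios:
  - {label: IL6_N100, a: 0.274, b: 0.125, c_prime: 0.0, n: 100, nsim: 1000}
  - {label: IL6_N250, a: 0.274, b: 0.125, c_prime: 0.0, n: 250, nsim: 1000}
  - {label: IL6_N500, a: 0.274, b: 0.125, c_prime: 0.0, n: 500, nsim: 1000}
  - {label: CRP_N100, a: 0.429, b: 0.108, c_prime: 0.0, n: 100, nsim: 1000}
  - {label: CRP_N250, a: 0.429, b: 0.108, c_prime: 0.0, n: 250, nsim: 1000}
  - {label: CRP_N500, a: 0.429, b: 0.108, c_prime: 0.0, n: 500, nsim: 1000}
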