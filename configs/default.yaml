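adjust_trait_p: true
alpha: 0.05
beta: 12.0
cyanoron_lfc: 1.0
de_fraction: 0.1
effect_lfc: 2.0
k_decay: 0.2
k_repair: 0.3
kinetics_noise_sd: 0.02
lfc_min: 1.0
merge_cut_height: 0.25
min_run: 4
min_size: 30
mode: signed
n_components: 2
n_cyanorons: 5
n_genes: 2634
seed: 0
share_t0: true
stages:
- simulate
- de
- network
- integrate
- cyanorons
- physiology
trait_noise_sd: 0.3
trait_p_threshold: 0.001
tree_cut_height: 0.9
use_tom: true
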