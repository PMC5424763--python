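# Complete annotated run configuration for `seedvision --config <file>`.
# Every key is optional; unset keys use the defaults shown here.

# --- segmentation ---
threshold: otsu      # "otsu" or a fixed integer gray threshold (0-255)
morph_radius: 2      # disk radius (px) of the opening that removes specks
min_area: 50         # components below this pixel area are dropped (dust)

# --- texture features ---
glcm_levels: 16      # gray-level quantization bins for the co-occurrence matrix
glcm_distance: 1     # pixel displacement of co-occurrence pairs
lsp_similarity_t: 10.0   # gray-level tolerance of the local similarity pattern
coarseness_kmax: 4   # largest window exponent (2^k) for Tamura coarseness

# --- network training ---
learning_rate: 0.01  # online gradient-descent step size (> 0)
mse_tolerance: 0.01  # stop when epoch-mean MSE falls below this (> 0)
max_epochs: 10000    # epoch budget; non-convergence is flagged, not fatal

# --- feature selection ---
sffs_max_steps: 30   # accepted add/remove steps before the search stops

# --- reproducibility ---
seed: 0              # master RNG seed (weight init, shuffling, synthesis)
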