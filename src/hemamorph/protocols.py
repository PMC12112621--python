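"""Constants of the validation protocol this package's evaluation stage mirrors.

The reference study design uses a multi-class smear benchmark split into
train/validation/test partitions, a small public two-class leukemia benchmark
for external checks, stratified five-fold cross-validation with a fixed seed,
and a 20% held-out fraction.
"""

# Reference multi-class benchmark partition sizes (images).
PRIMARY_PARTITIONS = {"training": 8380, "validation": 2600, "test": 1100}

# Pre-augmentation sample total of the reference benchmark.
PRE_AUGMENTATION_TOTAL = 12080

# External two-class benchmark subset sizes (images).
EXTERNAL_SUBSET_1 = 108   # segmentation subset
EXTERNAL_SUBSET_2 = 260   # classification subset

HELDOUT_FRACTION = 0.2
CV_FOLDS = 5
CV_SEED = 42
L2_LAMBDA = 0.01
ALPHA = 0.05
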