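"""Published replicate boundary slopes for the yeast remodeler strain panel.

SVM boundary slopes (replicates A and B) fitted in fPC score space on
large-gene MNase-seq profiles for wild type and chromatin-remodeler deletion
or depletion strains of *Saccharomyces cerevisiae*. These serve as reference
inputs for the boundary-slope comparison report; feeding them through
``nucphase.pipeline.comparison_table`` reproduces the published mean slopes
and s statistics.
"""

REFERENCE_STRAIN = "WT"

#: strain -> (replicate A slope, replicate B slope)
REPLICATE_SLOPES: dict[str, tuple[float, float]] = {
    "WT": (0.299, 0.055),
    "chd1": (0.834, 0.480),
    "isw1": (0.117, 0.329),
    "isw2": (0.133, 0.038),
    "rsc8": (0.377, 0.080),
    "isw1/chd1": (0.213, 0.283),
    "isw2/chd1": (1.406, 0.538),
    "chd1/rsc8": (0.031, 0.074),
    "isw1/isw2": (1.452, 1.074),
    "isw1/rsc8": (0.347, 0.072),
    "isw2/rsc8": (0.153, 0.567),
    "isw1/isw2/chd1": (0.112, 0.295),
    "isw1/chd1/rsc8": (0.216, 0.207),
    "isw2/chd1/rsc8": (0.057, 0.068),
    "isw1/isw2/rsc8": (0.466, 0.245),
    "isw1/isw2/chd1/rsc8": (0.066, 0.174),
}
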