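"""Shared settings for the analysis scripts: species list, era layout."""

from duphist.dating import Era, EraConfig

SPECIES = ["s1", "s2", "s3", "s4"]

# eras implied by the simulated clade: one recent WGD (Ks 0.3, s1 only) and
# one ancient shared duplication (Ks 1.5 + 2 x 0.1 speciation divergence);
# slot multiplicities 4:2:2:2 (recent WGD doubles s1 on top of the shared event)
ERAS = EraConfig(
    eras={sp: ([Era("recent", 0.3, 0.05, 0.8)] if sp == "s1" else [])
          + [Era("gamma", 1.7, 1.05, 3.5)] for sp in SPECIES},
    slots={"s1": 4, "s2": 2, "s3": 2, "s4": 2},
)
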