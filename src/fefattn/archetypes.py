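"""Built-in cell-archetype libraries.

Two sets are provided:

* :func:`study_population` — seven archetypes (four broad, three narrow)
  mirroring the cell classes FEF recordings separate into: they
  differentiate along attentional modulation, firing rate, and spiking
  regularity, with the third narrow class a high-rate, regular-spiking
  group whose waveform widths straddle the 250 us narrow/broad boundary.
  Drug parameters per iontophoresis agent: acetylcholine raises rates;
  muscarinic (scopolamine) and nicotinic (mecamylamine) blockade lower
  rates and raise gain variance; all three scale down the attention gain.
* :func:`separable_population` — seven strongly separated archetypes with
  low within-class variability, for planted-model recovery studies.
"""

from __future__ import annotations

from dataclasses import replace

from .synth import CellArchetype

# name, p2t_mean_us, p2t_sd_us, base_rate_hz, attention_gain, isi_shape, gain_var
_STUDY_BASE = [
    ("B1", 340.0, 25.0, 9.0, 1.45, 1.0, 0.30),
    ("B2", 370.0, 30.0, 4.0, 1.10, 0.7, 0.45),
    ("B3", 400.0, 30.0, 15.0, 1.25, 1.2, 0.20),
    ("B4", 430.0, 30.0, 7.0, 1.60, 1.6, 0.30),
    ("N1", 200.0, 15.0, 11.0, 1.50, 0.8, 0.15),
    ("N2", 225.0, 15.0, 5.0, 1.15, 1.0, 0.25),
    ("N3", 248.0, 28.0, 22.0, 1.30, 3.0, 0.10),
]

#: drug_gain, gain_var_drug_scale, attention_gain_drug_scale per agent
DRUG_PARAMS = {
    "ACh": dict(drug_gain=1.35, gain_var_drug_scale=1.0,
                attention_gain_drug_scale=0.7),
    "scopolamine": dict(drug_gain=0.70, gain_var_drug_scale=1.8,
                        attention_gain_drug_scale=0.6),
    "mecamylamine": dict(drug_gain=0.75, gain_var_drug_scale=1.6,
                         attention_gain_drug_scale=0.8),
}

#: attention lowers trial-to-trial gain variance
ATTEND_GV_SCALE = 0.6


def study_population(drug_name: str = "ACh") -> list[CellArchetype]:
    """The default seven-class population under one iontophoresis agent."""
    dp = DRUG_PARAMS[drug_name]
    return [
        CellArchetype(
            name=name,
            p2t_mean_us=p2t,
            p2t_sd_us=sd,
            base_rate_hz=rate,
            attention_gain=attn,
            isi_shape=kappa,
            gain_var=gv,
            gain_var_attend_scale=ATTEND_GV_SCALE,
            **dp,
        )
        for name, p2t, sd, rate, attn, kappa, gv in _STUDY_BASE
    ]


# name, p2t_mean_us, base_rate_hz, attention_gain, isi_shape, gain_var —
# patterns chosen mutually decorrelated across classes so waveform width,
# rate, regularity, attentional modulation and excitability variance are
# genuinely independent cluster dimensions
_SEPARABLE = [
    ("A1", 150.0, 35.0, 1.05, 6.0, 0.25),
    ("A2", 210.0, 8.0, 1.60, 0.5, 0.02),
    ("A3", 270.0, 18.0, 1.00, 2.0, 0.15),
    ("A4", 330.0, 10.0, 1.40, 1.0, 0.05),
    ("A5", 390.0, 28.0, 1.55, 0.6, 0.30),
    ("A6", 450.0, 14.0, 1.20, 4.0, 0.03),
    ("A7", 510.0, 50.0, 1.30, 1.5, 0.10),
]


def separable_population() -> list[CellArchetype]:
    """Seven well-separated archetypes for cluster-recovery studies."""
    return [
        CellArchetype(
            name=name,
            p2t_mean_us=p2t,
            p2t_sd_us=20.0,
            base_rate_hz=rate,
            attention_gain=attn,
            isi_shape=kappa,
            gain_var=gv,
            gain_var_attend_scale=1.0,
        )
        for name, p2t, rate, attn, kappa, gv in _SEPARABLE
    ]
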