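"""Scenario analyses as parameter transforms.

Both printed scenarios are pure transforms of the base parameter set and
therefore compose with the deterministic and probabilistic sensitivity
analyses (transform first, then override/sample).
"""

from __future__ import annotations

from dataclasses import replace

from .parameters import ModelParameters, ParameterError

SCENARIO_NAMES = ("base", "eval2-by-genotype", "im-dosing")


def scenario_genotype_specific_eval2(p: ModelParameters) -> ModelParameters:
    """Persistence at the second evaluation differs per genotype.

    Instead of the common fraction estimated from third TDM requests, each
    phenotype's (arm-specific) incorrect-at-first-evaluation fraction is
    reused as its probability of still being incorrectly dosed at the
    second evaluation.
    """
    return replace(p, scenario=replace(p.scenario, genotype_specific_eval2=True))


def scenario_im_dose_adaptation(p: ModelParameters,
                                fp_fraction: float = 0.38,
                                im_effect: float | None = None) -> ModelParameters:
    """Extend genotype-guided dosing to intermediate metabolizers.

    The genotyping arm applies the (assumed equal) effect to the IM
    supratherapeutic fraction; because a share of IM genotype calls is
    false positive, that share of the remaining incorrectly dosed IMs is
    dosed subtherapeutically instead of supratherapeutically — an extra
    branch of the tree that exists only in this scenario.  IMs also receive
    the guided start dose (60% of standard) for drug costing.
    """
    if not 0.0 <= fp_fraction <= 1.0:
        raise ParameterError(f"fp_fraction must be in [0, 1], got {fp_fraction}")
    effect = p.scenario.im_effect if im_effect is None else float(im_effect)
    return replace(p, scenario=replace(
        p.scenario, im_adaptation=True, im_fp_fraction=float(fp_fraction),
        im_effect=effect))


def get_scenario(name: str, p: ModelParameters, *,
                 im_fp_fraction: float = 0.38) -> ModelParameters:
    if name == "base":
        return p
    if name == "eval2-by-genotype":
        return scenario_genotype_specific_eval2(p)
    if name == "im-dosing":
        return scenario_im_dose_adaptation(p, im_fp_fraction)
    raise ParameterError(
        f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
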