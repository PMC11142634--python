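"""Multiple-testing threshold arithmetic used across the analysis battery."""

from __future__ import annotations


def bonferroni(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def study_thresholds(
    alpha: float = 0.05,
    n_bands: int = 5,
    n_networks: int = 7,
    n_nbs_models: int = 6,
) -> dict[str, float]:
    """The three corrected thresholds of the standard analysis battery.

    * per-band coupling contrasts: ``alpha / n_bands``
    * the NBS battery (fMRI + one model per EEG band): ``alpha / n_nbs_models``
    * subnetwork cells (bands x intrinsic networks): ``alpha / (n_bands * n_networks)``
    """
    return {
        "band_bonferroni": bonferroni(alpha, n_bands),
        "nbs_corrected": bonferroni(alpha, n_nbs_models),
        "subnetwork_bonferroni": bonferroni(alpha, n_bands * n_networks),
    }
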