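"""Feature-vector assembly from bilateral complex transmission spectra.

A recipe fixes four choices:

* **encoding** — how a complex 201-point spectrum becomes real features:
  ``magnitude`` (201), ``phase`` (201, radians wrapped to (-pi, pi]),
  ``mag_phase`` (402: magnitudes then phases), or ``complex_reim``
  (402: all real parts then all imaginary parts).
* **arm_mode** — ``average`` (complex spectra averaged pointwise across
  arms before encoding), ``concatenate`` (left then right encoded spectra),
  or ``separate`` (two vectors per subject, one per arm).
* **include_circumference** — append the wrist circumference(s) in cm, raw
  scale, at the end of the vector: the arm's own in ``separate`` mode, the
  mean of both in ``average`` mode, both (left then right) in
  ``concatenate`` mode.
* **normalize_eq1** — multiply the complex spectrum by the scalar
  Age/BMI before encoding. Because the factor is real and positive it
  scales magnitude and real/imaginary features but leaves phase features
  unchanged. Circumference features are never normalized.

The resulting lengths span 201 (single magnitude or phase spectrum) to 806
(both complex arm spectra concatenated plus both circumferences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Spectrum, SubjectRecord

__all__ = [
    "ENCODINGS",
    "ARM_MODES",
    "FeatureRecipe",
    "FeatureVector",
    "encode_spectrum",
    "normalize_eq1",
    "assemble",
    "feature_length",
]

ENCODINGS = ("magnitude", "phase", "mag_phase", "complex_reim")
ARM_MODES = ("average", "concatenate", "separate")


@dataclass(frozen=True)
class FeatureRecipe:
    """Encoding / arm-combination / normalization choices for one experiment."""

    encoding: str = "complex_reim"
    arm_mode: str = "separate"
    include_circumference: bool = True
    normalize_eq1: bool = False

    def __post_init__(self) -> None:
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}; expected one of {ENCODINGS}")
        if self.arm_mode not in ARM_MODES:
            raise ValueError(f"unknown arm_mode {self.arm_mode!r}; expected one of {ARM_MODES}")


@dataclass(frozen=True)
class FeatureVector:
    """A flat numeric vector with its provenance."""

    values: np.ndarray
    subject_id: str
    arm_tag: str  # "left", "right" or "both"
    recipe: FeatureRecipe

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def _encoded_len_per_spectrum(encoding: str, n_points: int) -> int:
    return n_points if encoding in ("magnitude", "phase") else 2 * n_points


def feature_length(recipe: FeatureRecipe, n_points: int = 201) -> int:
    """Closed-form length of an assembled vector under ``recipe``."""
    per = _encoded_len_per_spectrum(recipe.encoding, n_points)
    spectral = 2 * per if recipe.arm_mode == "concatenate" else per
    if recipe.include_circumference:
        spectral += 2 if recipe.arm_mode == "concatenate" else 1
    return spectral


def _encode_values(values: np.ndarray, encoding: str) -> np.ndarray:
    values = np.asarray(values, dtype=complex)
    if encoding == "magnitude":
        return np.abs(values)
    if encoding == "phase":
        return np.angle(values)  # wrapped to (-pi, pi]
    if encoding == "mag_phase":
        return np.concatenate([np.abs(values), np.angle(values)])
    if encoding == "complex_reim":
        return np.concatenate([values.real, values.imag])
    raise ValueError(f"unknown encoding {encoding!r}")


def encode_spectrum(spectrum: Spectrum | np.ndarray, encoding: str) -> np.ndarray:
    """Encode a complex spectrum (or raw complex array) into real features."""
    values = spectrum.values if isinstance(spectrum, Spectrum) else spectrum
    return _encode_values(values, encoding)


def normalize_eq1(spectrum_values: np.ndarray, age: float, bmi: float) -> np.ndarray:
    """Scale a complex spectrum by the subject's Age/BMI risk factor."""
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    return np.asarray(spectrum_values, dtype=complex) * (age / bmi)


def assemble(subject: SubjectRecord, recipe: FeatureRecipe) -> list[FeatureVector]:
    """Build the feature vector(s) for one subject.

    Returns one vector (``average``/``concatenate`` modes, arm_tag
    ``"both"``) or two (``separate`` mode, tagged ``"left"``/``"right"``).
    """

    def prepared(values: np.ndarray) -> np.ndarray:
        if recipe.normalize_eq1:
            values = normalize_eq1(values, subject.age, subject.bmi)
        return _encode_values(values, recipe.encoding)

    left = subject.spectrum("S21", "left").values
    right = subject.spectrum("S21", "right").values

    if recipe.arm_mode == "average":
        feats = prepared(0.5 * (left + right))
        if recipe.include_circumference:
            mean_circ = 0.5 * (subject.circumference_left + subject.circumference_right)
            feats = np.concatenate([feats, [mean_circ]])
        return [FeatureVector(feats, subject.subject_id, "both", recipe)]

    if recipe.arm_mode == "concatenate":
        feats = np.concatenate([prepared(left), prepared(right)])
        if recipe.include_circumference:
            feats = np.concatenate(
                [feats, [subject.circumference_left, subject.circumference_right]]
            )
        return [FeatureVector(feats, subject.subject_id, "both", recipe)]

    # separate: one vector per arm, each with its own circumference
    out = []
    for arm, values, circ in (
        ("left", left, subject.circumference_left),
        ("right", right, subject.circumference_right),
    ):
        feats = prepared(values)
        if recipe.include_circumference:
            feats = np.concatenate([feats, [circ]])
        out.append(FeatureVector(feats, subject.subject_id, arm, recipe))
    return out
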