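"""Bundled worked example: monitoring sample EEC2010_Site 102.

This is the published demonstration case for the sediment-change test: a 2010
monitoring sample from site 102 in the eastern English Channel dredging
region (extraction area 473/2), tested against the sediment envelope of its
baseline faunal-physical group B1a_4 (n = 948 reference samples). The sample
is known from earlier survey work to have been modified by dredging — an
excess of fine sand — so it should, and does, fail the test.
"""

from __future__ import annotations

import numpy as np

from rsmp.change_test import TestSample
from rsmp.envelopes import GroupKey, SedimentEnvelope

#: Fraction order: S/C, fS, mS, cS, fG, mG, cG (% by weight).
EEC2010_SITE102_V = np.array([1.9, 17.8, 36.3, 23.7, 13.4, 3.9, 3.1])

B1A4_MEAN = np.array([1.0, 4.3, 24.2, 26.8, 22.8, 12.4, 8.6])

B1A4_N = 948

#: Unbiased sample covariance of the 7 fractions over the B1a_4 reference
#: samples. Rows sum to ~0 — the closure constraint of compositional data —
#: so the matrix is near-singular and the test must use a pseudo-inverse.
B1A4_COV = np.array(
    [
        [2.1, 0.9, -1.4, -2.7, -0.6, 1.2, 0.6],
        [0.9, 6.4, 9.2, -10.2, -4.1, 0.3, -2.6],
        [-1.4, 9.2, 58.5, 1.8, -15.7, -15.7, -36.8],
        [-2.7, -10.2, 1.8, 106.6, 5.9, -43.4, -58.0],
        [-0.6, -4.1, -15.7, 5.9, 34.7, 6.6, -26.8],
        [1.2, 0.3, -15.7, -43.4, 6.6, 41.2, 9.9],
        [0.6, -2.6, -36.8, -58.0, -26.8, 9.9, 113.7],
    ]
)


def worked_example() -> tuple[TestSample, SedimentEnvelope]:
    """The EEC2010_Site 102 test sample and its B1a_4 baseline envelope."""
    sample = TestSample(
        sample_id="EEC2010_Site 102", v=EEC2010_SITE102_V.copy(), group="B1a_4"
    )
    envelope = SedimentEnvelope(
        key=GroupKey("B1a", 4), n=B1A4_N, mean=B1A4_MEAN.copy(), cov=B1A4_COV.copy()
    )
    return sample, envelope
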