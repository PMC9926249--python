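"""Equilibrium HgII-particle partitioning and remineralization release.

HgP is diagnosed from the total divalent pool with a linear partition
coefficient against the local POC concentration; the particulate fraction is
Kd*POC/(1 + Kd*POC).  Remineralization releases particle-bound Hg back to
the dissolved divalent pool at a rate tracking the local specific carbon
remineralization rate OCRR/POC.
"""
from __future__ import annotations

import numpy as np

from .params import PartitionParams


def particulate_fraction(poc, p: PartitionParams = PartitionParams()):
    poc = np.asarray(poc, float)
    if np.any(poc < 0):
        raise ValueError("POC must be >= 0")
    kp = p.kd * poc
    return kp / (1.0 + kp)


def partition(hg2_total, poc, p: PartitionParams = PartitionParams()):
    """Split total divalent Hg into (dissolved, particle-bound), pM.

    The two parts sum to the input exactly; the particulate share is
    strictly increasing in POC and zero where POC is zero.
    """
    hg2_total = np.asarray(hg2_total, float)
    if np.any(hg2_total < 0):
        raise ValueError("HgII must be >= 0")
    f = particulate_fraction(poc, p)
    hgp = hg2_total * f
    return hg2_total - hgp, hgp


def remineralize(hgp, ocrr, poc, p: PartitionParams = PartitionParams(),
                 dt: float = 1.0):
    """Release HgP to dissolved HgII as organic carbon remineralizes.

    Release over ``dt`` days follows exponential decay at the specific rate
    remin_scale * OCRR/POC (d-1); the returned (HgP', released) pair sums to
    the input exactly.  OCRR > 0 where POC = 0 is inconsistent forcing.
    """
    hgp = np.asarray(hgp, float)
    ocrr = np.asarray(ocrr, float)
    poc = np.asarray(poc, float)
    if np.any(hgp < 0) or np.any(ocrr < 0) or np.any(poc < 0):
        raise ValueError("inputs must be >= 0")
    if np.any((ocrr > 0) & (poc == 0)):
        raise ValueError("inconsistent forcing: OCRR > 0 where POC = 0")
    rate = np.zeros(np.broadcast_shapes(ocrr.shape, poc.shape))
    ok = poc > 0
    rate[ok] = p.remin_scale * (ocrr / np.where(ok, poc, 1.0))[ok]
    remaining = hgp * np.exp(-rate * dt)
    return remaining, hgp - remaining
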