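"""Shared fixtures: simulated cohorts and rendered scan banks.

Scan banks are cached per (n_scans, seed) so that several tests can
share one rendering pass; everything is generated at test time from the
package's own simulator.
"""

from __future__ import annotations

import numpy as np
import pytest

from octneed.cohort import CohortConfig, DeviceProfile, simulate_cohort
from octneed.datasets import _scan_seed
from octneed.render import render_scan


@pytest.fixture(scope="session")
def device():
    return DeviceProfile()


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient default-condition cohort."""
    return simulate_cohort(CohortConfig(n_patients=40, seed=123))


class ScanBank:
    """Lazy cache of rendered (state, volume, mask) triples per cohort."""

    def __init__(self):
        self._cache = {}

    def scans(self, n_scans: int, seed: int, device: DeviceProfile):
        key = (n_scans, seed)
        if key not in self._cache:
            n_patients = (n_scans + 1) // 2
            cohort = simulate_cohort(CohortConfig(n_patients=n_patients, seed=seed))
            out = []
            for i, p in enumerate(cohort):
                for week in (8, 16):
                    if len(out) >= n_scans:
                        break
                    state = p.fluid_at_week(week)
                    vol, mask = render_scan(state, device, _scan_seed(seed, i, week))
                    out.append((state, vol, mask))
            self._cache[key] = out
        return self._cache[key]


@pytest.fixture(scope="session")
def scan_bank():
    return ScanBank()
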