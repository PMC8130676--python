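"""Shared fixtures: experiment-condition objects used across the suite."""

from __future__ import annotations

import pytest

from afsrheo.fluidprops import FluidState
from afsrheo.forcemodel import AcousticForceParams, BeadSpec
from afsrheo.hydrodynamics import WallDragSpec
from afsrheo.rheology import ImmersionGeometry, OscProtocol
from afsrheo.viscomodels import GKVParams


@pytest.fixture(scope="session")
def fluid36() -> FluidState:
    """Water at the 36 degC measurement set point."""
    return FluidState(temperature=36.0)


@pytest.fixture(scope="session")
def bead() -> BeadSpec:
    """Default 10 um polystyrene probe bead."""
    return BeadSpec()


@pytest.fixture(scope="session")
def brenner_drag(bead) -> WallDragSpec:
    return WallDragSpec(method="brenner", bead_radius=bead.radius)


@pytest.fixture(scope="session")
def faxen_drag(bead) -> WallDragSpec:
    return WallDragSpec(method="faxen", bead_radius=bead.radius)


@pytest.fixture(scope="session")
def no_drag(bead) -> WallDragSpec:
    return WallDragSpec(method="none", bead_radius=bead.radius)


@pytest.fixture(scope="session")
def reference_profile() -> AcousticForceParams:
    """Published Brenner-corrected calibration triple (f0, k_p, phi_p)."""
    return AcousticForceParams(f0=488.189, k_p=0.046, phi_p=0.799)


@pytest.fixture(scope="session")
def huvec_gkv() -> GKVParams:
    """Mean GKV triple measured on the HUVEC monolayer."""
    return GKVParams(G0=1033.0, alpha=0.850, beta=0.058)


@pytest.fixture(scope="session")
def default_protocol() -> OscProtocol:
    return OscProtocol()


@pytest.fixture(scope="session")
def default_geometry() -> ImmersionGeometry:
    return ImmersionGeometry()
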