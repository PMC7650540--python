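"""Shared fixtures: small synthetic instances with known ground truth."""

from __future__ import annotations

import pytest

from panmet.synthdata import (
    PanGenomeParams,
    generate_pangenome,
    generate_true_network,
)


@pytest.fixture(scope="session")
def small_pangenome():
    """5 species, planted core/shell/cloud families, wide identity gap."""
    return generate_pangenome(
        PanGenomeParams(
            n_species=5,
            core_size=10,
            shell_families=6,
            p_shell=0.5,
            cloud_rate=2,
            within_family_identity=0.9,
            between_family_identity=0.2,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def small_network():
    """3 species toy genus: true models + superset universal database."""
    return generate_true_network(3, db_size=30, shared_fraction=0.5, seed=7)
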