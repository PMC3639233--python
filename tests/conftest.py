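import numpy as np
import pytest

import hybridrx as hx


@pytest.fixture(scope="session")
def one_gene():
    return hx.benchmark_fixture("one_gene")


@pytest.fixture(scope="session")
def two_gene_repression():
    return hx.benchmark_fixture("two_gene_repression")


@pytest.fixture(scope="session")
def two_gene_pf():
    return hx.benchmark_fixture("two_gene_positive_feedback")


@pytest.fixture(scope="session")
def three_gene():
    return hx.benchmark_fixture("three_gene")


@pytest.fixture(scope="session")
def one_gene_params(one_gene):
    return hx.OneGeneParams(
        beta1=1.0, gamma1=0.04, pd=one_gene.pd, reg=one_gene.regimen
    )


def regimen_with(reg, **kw):
    """A copy of a regimen with overrides (lambda_a rederived)."""
    from dataclasses import replace

    kw.setdefault("lambda_a", None)
    return replace(reg, **kw)
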