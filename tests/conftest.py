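import pytest

from metcentric import apply_scenario, make_fixture, solve_fba

FIXTURE_KINDS = ["chain", "diamond", "cycle", "bypass", "mini_core"]


@pytest.fixture(params=FIXTURE_KINDS)
def bundle(request):
    return make_fixture(request.param)


@pytest.fixture
def solved(bundle):
    """(bundle, problem, flux distribution) for each fixture kind."""
    problem = apply_scenario(bundle.model, bundle.scenario)
    fd = solve_fba(problem)
    assert fd.status == "optimal"
    return bundle, problem, fd


def solve_kind(kind: str, **params):
    bundle = make_fixture(kind, **params)
    problem = apply_scenario(bundle.model, bundle.scenario)
    fd = solve_fba(problem)
    assert fd.status == "optimal"
    return bundle, problem, fd
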