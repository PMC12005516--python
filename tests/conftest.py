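import copy

import pytest

import insulinshift as ins


def collapse_intervals(params):
    """Parameter set with every uncertainty interval collapsed to its point."""
    cfg = copy.deepcopy(params.config)

    def collapse(node):
        if isinstance(node, dict):
            if set(node) <= {"mean", "lo", "hi"} and ("lo" in node or "mean" in node):
                m = node.get("mean", 0.5 * (node["lo"] + node["hi"]))
                return {"mean": m, "lo": m, "hi": m}
            return {k: collapse(v) for k, v in node.items()}
        return node

    for section in ("baseline", "disutility", "therapies"):
        cfg[section] = collapse(cfg[section])
    cfg["baseline"]["mortality"] = copy.deepcopy(params.config["baseline"]["mortality"])
    return ins.ModelParams(cfg)


@pytest.fixture(scope="session")
def params():
    return ins.load_params()


@pytest.fixture(scope="session")
def profiles():
    """The 14 per-country profile fixtures (no pooled pseudo-country)."""
    return ins.load_country_profiles()


@pytest.fixture(scope="session")
def overall():
    return ins.load_country_profiles(include_overall=True)["OVERALL"]


@pytest.fixture(scope="session")
def pooled_pop(overall):
    """Synthetic pooled insulin-user cohort matching the overall marginals."""
    return ins.generate_population(overall, 4000, seed=7)


@pytest.fixture(scope="session")
def glp1(params):
    return ins.build_therapy("glp1ra_inj", params)


@pytest.fixture(scope="session")
def sglt2i(params):
    return ins.build_therapy("sglt2i", params)


@pytest.fixture(scope="session")
def combo(params):
    return ins.build_therapy("combo", params)
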