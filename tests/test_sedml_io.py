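import pytest
from lxml import etree

from omexsim import fixtures
from omexsim.errors import UnsupportedFeatureError
from omexsim.inline_omex import parse_document
from omexsim.model_lang import parse_model
from omexsim.sedml_io import (SEDML_NS_WRITE, load_kisao_map, read_sedml,
                              write_sedml)
from omexsim.sim_lang import parse_simulation


def _spec_with_paths(name):
    doc = parse_document(fixtures.generate_fixture(name))
    models = {}
    paths = {}
    for i, section in enumerate(doc.model_sections(), start=1):
        m = parse_model(section.text)
        models[m.id] = m
        paths[m.id] = section.archive_path
    specs = [parse_simulation(s.text, set(models))
             for s in doc.simulation_sections()]
    return specs, paths, models


@pytest.mark.parametrize("name", fixtures.FIXTURE_NAMES)
def test_read_write_roundtrip_on_fixture_specs(name):
    specs, paths, models = _spec_with_paths(name)
    id_by_path = {v: k for k, v in paths.items()}
    for spec in specs:
        xml = write_sedml(spec, paths, model_docs=models)
        again = read_sedml(xml)
        for m in again.model_refs:   # paths map back to model-section ids
            m.source = id_by_path.get(m.source, m.source)
        assert again == spec


def test_kisao_mapping_is_a_bijection():
    table = load_kisao_map()["algorithms"]
    assert set(table) == {"lsoda", "cvode", "gillespie", "rk4"}
    assert len(set(table.values())) == len(table)
    assert all(v.startswith("KISAO:") and len(v.split(":")[1]) == 7
               for v in table.values())


def test_uniform_timecourse_attributes():
    spec = parse_simulation(
        'm1 = model "m.xml"\n'
        "sim1 = simulate uniform(0, 120, 1000)\n"
        "t1 = run sim1 on m1")
    xml = write_sedml(spec, {})
    root = etree.fromstring(xml.encode())
    (utc,) = root.iter(f"{{{SEDML_NS_WRITE}}}uniformTimeCourse")
    assert utc.get("initialTime") == "0"
    assert utc.get("outputStartTime") == "0"
    assert utc.get("outputEndTime") == "120"
    assert utc.get("numberOfPoints") == "1000"
    again = read_sedml(xml)
    assert again.simulations[0].t_end == 120.0
    assert again.simulations[0].n_points == 1000


def test_two_model_refs_share_one_source():
    spec = parse_simulation(
        'm1 = model "m.xml" with k1 = 0.5\n'
        'm2 = model "m.xml" with k1 = 1.5\n'
        "sim1 = simulate uniform(0, 4, 10)\n"
        "t1 = run sim1 on m1\n"
        "t2 = run sim1 on m2")
    root = etree.fromstring(write_sedml(spec, {}).encode())
    models = list(root.iter(f"{{{SEDML_NS_WRITE}}}model"))
    assert len(models) == 2
    assert models[0].get("source") == models[1].get("source") == "m.xml"
    changes = list(root.iter(f"{{{SEDML_NS_WRITE}}}changeAttribute"))
    assert sorted(c.get("newValue") for c in changes) == ["0.5", "1.5"]


def test_algorithm_parameters_encoded():
    spec = parse_simulation(
        'm1 = model "m.xml"\n'
        "sim1 = simulate uniform(0, 10, 10)\n"
        "sim1.variable_step_size = true\n"
        "sim1.relative_tolerance = 1e-09\n"
        "sim1.seed = 42\n"
        "t1 = run sim1 on m1")
    xml = write_sedml(spec, {})
    again = read_sedml(xml)
    s = again.simulations[0]
    assert s.variable_step_size and s.rtol == 1e-9 and s.seed == 42


def test_empty_spec_roundtrip():
    spec = parse_simulation("")
    xml = write_sedml(spec, {})
    assert read_sedml(xml) == spec


def test_log10_datagen_mathml_roundtrip():
    spec = parse_simulation(
        'm1 = model "m.xml"\n'
        "sim1 = simulate uniform(0, 10, 10)\n"
        "t1 = run sim1 on m1\n"
        'plot "log" log10(time) vs log10(S)')
    xml = write_sedml(spec, {})
    assert "logbase" in xml
    again = read_sedml(xml)
    mathes = {g.math for g in again.data_generators}
    assert ("call", "log10", (("sym", "t1.S"),)) in mathes
    assert ("call", "log10", (("sym", "t1.time"),)) in mathes


def test_plot3d_unsupported():
    xml = f"""<?xml version="1.0"?>
<sedML xmlns="{SEDML_NS_WRITE}" level="1" version="2">
 <listOfOutputs><plot3D id="p"/></listOfOutputs>
</sedML>"""
    with pytest.raises(UnsupportedFeatureError, match="plot3D"):
        read_sedml(xml)


def test_functional_range_unsupported():
    xml = f"""<?xml version="1.0"?>
<sedML xmlns="{SEDML_NS_WRITE}" level="1" version="2">
 <listOfTasks>
  <repeatedTask id="r" range="fr">
   <listOfRanges><functionalRange id="fr"/></listOfRanges>
   <listOfSubTasks><subTask order="1" task="t"/></listOfSubTasks>
  </repeatedTask>
 </listOfTasks>
</sedML>"""
    with pytest.raises(UnsupportedFeatureError, match="functionalRange"):
        read_sedml(xml)
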