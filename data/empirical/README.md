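# Empirical inputs (user-supplied, not redistributed)

The published-value reproduction (`tests/test_acceptance.py::
test_published_value_reproduction`) runs the full analysis on the study's
own data, which cannot be bundled here.  To enable it, place in this
directory:

- `tree.nwk` — the DNA-only node-dated MCC mammal timetree (Upham et al.),
  pruned to the sampled species, with the fossil tips grafted
  (*Urotrichus giganteus*, *Tegulariscaptor minor*; any of the Tree1A /
  Tree1B / Tree2 placements).
- `traits.csv` — one row per species (index column `species`) with at
  least: `bvtv` (humeral head bone volume fraction), `compactness` (mean
  global diaphyseal compactness), `csa_mm2` (mean total cross-sectional
  area), `body_mass_g` (database mass; empty for fossils), `lifestyle`
  (`subterranean` / `non_subterranean`), `fossorial_talpid` (boolean).
  These are the study's supplementary-table parameters.
- `clade_map.yaml` — mapping `acquisition name -> [member tip names]` for
  the 11 sampled independent subterranean acquisitions; talpid
  acquisitions must contain "talpid" in their name so the
  exclusion re-run can find them.

Without these files the test fails with a message (rather than passing
vacuously); everything else in the package is self-contained.
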