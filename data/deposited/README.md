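Place the deposited coordinate files here to enable the crystal-structure
checks (they are not redistributed with this package):

  6zpm.pdb (or .cif)  - T. cruzi KKT4 coiled-coil dimer
  6zpj.pdb (or .cif)  - L. mexicana KKT4 coiled-coil dimer
  6zpk.pdb (or .cif)  - T. brucei KKT4 BRCT domain
  3fa2.pdb (or .cif)  - BRCT comparison entry

With these present, tests/test_acceptance.py's deposited-entries test and
scripts/acceptance.py compute the inter-helical distance, pitch, heptad
counts and cross-structure RMSDs.
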