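# Local structure cache

Place copies of the seven public MET kinase-domain PDB entries here to
enable the real-structure survey (tests in `tests/test_acceptance.py` and
the real-entry section of `scripts/acceptance.py`):

    1R1W  2G15  3F66  4KNB  3Q6W  3R7O  4IWD

With network access this is one command from the repository root:

    metconf fetch 1R1W 2G15 3F66 4KNB 3Q6W 3R7O 4IWD

The files are public-domain crystallographic depositions and are not
redistributed with the package; everything else in the test suite runs on
generated fixtures and needs nothing in this directory.
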