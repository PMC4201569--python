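# Cryptic splice-site 4-mer variants (positions -3..+1 around an
# insertion point) accepted by the proto-splice classifier in addition
# to observed authentic junctions and the MAG|G motif.
#
# One motif per line; IUPAC ambiguity codes allowed.  The default list
# is intentionally empty: curated cryptic-variant catalogues are
# compiled for human disease genes and no dinoflagellate-specific list
# exists, so entries are left to the user.
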