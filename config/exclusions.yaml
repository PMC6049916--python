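# Signature-set exclusion profiles for `compute_indices(excluded_tags=...)`.
#
# v1: the default — every publication-specific signature set is used.
# v2: a slot for excluding weaker cell-type-specific gene sets. Which sets
#     count as "weak" depends on the marker database in use and is not
#     enumerated here; populate the list with the publication tags you wish
#     to drop, e.g.
#       v2:
#         - Oligodendrocyte_Immature_SomeStudy_2014
profiles:
  v1: []
  v2: []
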