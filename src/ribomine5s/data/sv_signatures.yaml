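# Signature segments (alignment columns on the master row) for the four
# spacer structural variants: group-specific indels I and II and the GC
# duplication. The shipped reference alignment is SYNTHETIC (the GC
# duplication is represented by an 8-bp segment so that alignment can
# localize it); point these paths/ranges at a real alignment to type
# real data.
reference: petota_sv_reference.synthetic.afa
master_row: master
segments:
  indel_I: [60, 72]
  indel_II: [122, 131]
  GC_DUP: [161, 169]
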