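label,n_games,n_concussions_total,n_concussions_video
2006-2010,4920,301,231
2014-2019,6232,516,457
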