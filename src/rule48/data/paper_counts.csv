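cohort,variable,numerator,denominator,denominator_kind
2006-2010,open ice,108,231,events_with_video
2006-2010,offensive,79,230,events_with_video
2006-2010,neutral,45,230,events_with_video
2006-2010,defensive,106,230,events_with_video
2006-2010,all body checks,173,231,events_with_video
2006-2010,body checks to head,113,231,events_with_video
2006-2010,shoulder,78,231,events_with_video
2006-2010,glove,8,231,events_with_video
2006-2010,arm,27,231,events_with_video
2006-2010,lateral hit to head,80,231,events_with_video
2006-2010,first period,117,231,events_with_video
2006-2010,puck possession,46,231,events_with_video
2006-2010,penalty called,60,220,events_with_video
2006-2010,forward,149,231,events_with_video
2006-2010,defense,61,194,events_with_video
2006-2010,goalie,4,194,events_with_video
2014-2019,open ice,167,455,events_with_video
2014-2019,offensive,167,457,events_with_video
2014-2019,neutral,95,457,events_with_video
2014-2019,defensive,195,457,events_with_video
2014-2019,all body checks,307,455,events_with_video
2014-2019,body checks to head,149,455,events_with_video
2014-2019,shoulder,91,455,events_with_video
2014-2019,glove,8,455,events_with_video
2014-2019,arm,50,455,events_with_video
2014-2019,lateral hit to head,61,455,events_with_video
2014-2019,first period,158,440,events_with_video
2014-2019,puck possession,77,455,events_with_video
2014-2019,penalty called,96,457,events_with_video
2014-2019,forward,281,457,events_with_video
2014-2019,defense,146,457,events_with_video
2014-2019,goalie,30,457,events_with_video
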