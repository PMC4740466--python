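tag_id,tagging_site,sex,fork_length_cm,tagging_date,days_monitored,days_detected,max_consecutive_days,reefs_visited,migration_flag,roaming_index_printed,residency_index_printed
T1,Rib,F,195,2012-10-08,737,73,11,7,M-R,0.41,0.10
T2,Rib,F,200,2012-10-08,737,83,8,5,,0.29,0.11
T3,Rib,F,150,2012-10-09,736,6,4,3,M-R,0.18,0.01
T4,Lodestone,M,215,2012-10-11,734,473,24,11,M,0.65,0.64
T5,John Brewer,M,185,2012-10-17,728,22,4,4,,0.24,0.03
T6,John Brewer,F,182,2012-10-17,728,107,12,5,,0.29,0.15
T7,John Brewer,F,208,2012-10-17,728,188,15,13,,0.76,0.26
T8,John Brewer,F,235,2012-10-18,727,41,5,9,M-R,0.53,0.06
T9,John Brewer,M,212,2012-10-19,726,4,2,5,,0.29,0.01
T10,John Brewer,F,172,2012-10-19,726,3,2,4,M-R,0.24,<0.01
T11,Keeper,F,269,2013-02-11,611,5,3,5,,0.29,0.01
T12,Rib,F,195,2013-02-16,606,116,7,4,,0.24,0.19
T13,Lodestone,F,176,2013-02-18,604,24,8,3,,0.18,0.04
T14,Wheeler,M,205,2013-04-23,540,374,29,4,,0.24,0.69
T15,Helix,F,237,2013-04-25,538,34,15,7,M-R,0.41,0.06
T16,Helix,F,230,2013-04-25,538,274,21,10,,0.59,0.51
T17,Lodestone,M,190,2013-04-26,537,80,8,9,M-R,0.53,0.15
T18,Lodestone,F,225,2013-04-27,536,139,18,10,M-R,0.59,0.26
T19,Centipede,M,185,2013-07-30,442,113,25,8,,0.47,0.26
T20,Lodestone,M,176,2013-08-04,437,6,5,4,,0.24,0.01
T21,Lodestone,F,215,2013-08-05,436,41,14,8,,0.47,0.09
T22,Lodestone,F,235,2013-08-06,435,150,14,11,,0.65,0.34
T23,Bramble,M,210,2013-09-23,387,18,4,4,M-R,0.24,0.05
T24,Bramble,F,164,2013-09-23,387,111,15,6,M-R,0.35,0.29
T25,Keeper,F,220,2013-09-26,384,50,15,10,,0.59,0.13
T26,Davies,F,165,2013-09-30,380,11,10,5,M-R,0.29,0.03
T27,Broadhurst,F,200,2013-09-30,380,91,10,7,M-R,0.41,0.24
T28,Lodestone,F,185,2013-11-17,332,39,14,5,,0.29,0.12
T29,Lodestone,F,198,2013-11-19,330,123,54,7,M-R,0.41,0.37
T30,Lodestone,F,182,2013-11-19,330,170,11,11,,0.65,0.52
T31,Lodestone,F,222,2013-11-20,329,76,7,12,M,0.71,0.23
T32,Helix,F,207,2014-02-15,242,14,2,8,M-R,0.47,0.06
T33,Lodestone,F,213,2014-02-19,238,1,1,2,M,0.12,<0.01
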