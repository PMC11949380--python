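period,subgroup,lifetime_risk_pct
1996-2000,total,69
2001-2005,total,71
2006-2010,total,72
2011-2015,total,72
2016-2020,total,72
1996-2000,women,68
2001-2005,women,70
2006-2010,women,71
2011-2015,women,71
2016-2020,women,71
1996-2000,men,69
2001-2005,men,71
2006-2010,men,72
2011-2015,men,73
2016-2020,men,73
1996-2000,women/basic,71
2001-2005,women/basic,73
2006-2010,women/basic,74
2011-2015,women/basic,74
2016-2020,women/basic,74
1996-2000,women/secondary,63
2001-2005,women/secondary,66
2006-2010,women/secondary,67
2011-2015,women/secondary,67
2016-2020,women/secondary,67
1996-2000,women/tertiary,58
2001-2005,women/tertiary,61
2006-2010,women/tertiary,62
2011-2015,women/tertiary,63
2016-2020,women/tertiary,63
1996-2000,men/basic,71
2001-2005,men/basic,72
2006-2010,men/basic,74
2011-2015,men/basic,74
2016-2020,men/basic,74
1996-2000,men/secondary,66
2001-2005,men/secondary,68
2006-2010,men/secondary,68
2011-2015,men/secondary,69
2016-2020,men/secondary,69
1996-2000,men/tertiary,68
2001-2005,men/tertiary,70
2006-2010,men/tertiary,71
2011-2015,men/tertiary,71
2016-2020,men/tertiary,72
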