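period,subgroup,tle,e_free,e_cvd,pct_free
1996-2000,total,38.3,30.5,7.8,80
2001-2005,total,39.6,31.1,8.5,79
2006-2010,total,40.9,32.0,8.9,78
2011-2015,total,41.7,32.7,9.0,78
2016-2020,total,42.5,33.3,9.2,78
1996-2000,women,41.3,33.9,7.4,82
2001-2005,women,42.4,34.4,8.0,81
2006-2010,women,43.6,35.2,8.4,81
2011-2015,women,44.3,35.8,8.5,81
2016-2020,women,44.9,36.3,8.6,81
1996-2000,men,35.1,27.0,8.1,77
2001-2005,men,36.7,27.9,8.8,76
2006-2010,men,37.9,28.7,9.2,76
2011-2015,men,39.2,29.7,9.5,76
2016-2020,men,40.0,30.3,9.7,76
1996-2000,women/basic,39.9,32.6,7.3,82
2001-2005,women/basic,40.9,32.9,8.0,80
2006-2010,women/basic,42.2,33.7,8.5,80
2011-2015,women/basic,42.7,34.1,8.6,80
2016-2020,women/basic,43.2,34.5,8.7,80
1996-2000,women/secondary,42.2,34.6,7.6,82
2001-2005,women/secondary,43.2,34.7,8.5,80
2006-2010,women/secondary,44.1,35.1,9.0,80
2011-2015,women/secondary,44.6,35.6,9.0,80
2016-2020,women/secondary,45.0,36.0,9.0,80
1996-2000,women/tertiary,43.6,36.7,6.9,84
2001-2005,women/tertiary,44.6,36.9,7.7,83
2006-2010,women/tertiary,45.6,37.3,8.3,82
2011-2015,women/tertiary,46.4,37.8,8.6,81
2016-2020,women/tertiary,47.0,38.2,8.8,81
1996-2000,men/basic,33.3,25.4,7.9,76
2001-2005,men/basic,34.7,26.1,8.6,75
2006-2010,men/basic,35.8,26.8,9.0,75
2011-2015,men/basic,36.8,27.6,9.2,75
2016-2020,men/basic,37.5,28.1,9.4,75
1996-2000,men/secondary,35.8,27.2,8.6,76
2001-2005,men/secondary,37.1,27.8,9.3,75
2006-2010,men/secondary,38.0,28.5,9.5,75
2011-2015,men/secondary,39.2,29.4,9.8,75
2016-2020,men/secondary,39.9,29.9,10.0,75
1996-2000,men/tertiary,39.0,30.1,8.9,77
2001-2005,men/tertiary,40.3,30.8,9.5,76
2006-2010,men/tertiary,41.4,31.5,9.9,76
2011-2015,men/tertiary,42.5,32.3,10.2,76
2016-2020,men/tertiary,43.3,32.9,10.4,76
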