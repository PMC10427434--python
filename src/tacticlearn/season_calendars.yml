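# Season windows for the five top European divisions, 2012/13-2016/17.
# Editable: exact boundary dates only decide which early-season games are
# excluded by the moving-window eligibility rule.  Break intervals mark the
# Bundesliga winter pause, compressed to break_target_days by
# assign_seasons_and_breaks so day-windows always contain prior games.
break_target_days: 10
divisions:
  Premier League:
    seasons:
      2012/13: {start: 2012-08-18, end: 2013-05-19}
      2013/14: {start: 2013-08-17, end: 2014-05-11}
      2014/15: {start: 2014-08-16, end: 2015-05-24}
      2015/16: {start: 2015-08-08, end: 2016-05-17}
      2016/17: {start: 2016-08-13, end: 2017-05-21}
  Bundesliga:
    seasons:
      2012/13: {start: 2012-08-24, end: 2013-05-18}
      2013/14: {start: 2013-08-09, end: 2014-05-10}
      2014/15: {start: 2014-08-22, end: 2015-05-23}
      2015/16: {start: 2015-08-14, end: 2016-05-14}
      2016/17: {start: 2016-08-26, end: 2017-05-20}
    breaks:
      2012/13: {start: 2012-12-16, end: 2013-01-18}
      2013/14: {start: 2013-12-22, end: 2014-01-24}
      2014/15: {start: 2014-12-21, end: 2015-01-30}
      2015/16: {start: 2015-12-20, end: 2016-01-22}
      2016/17: {start: 2016-12-22, end: 2017-01-20}
  La Liga:
    seasons:
      2012/13: {start: 2012-08-18, end: 2013-06-01}
      2013/14: {start: 2013-08-17, end: 2014-05-18}
      2014/15: {start: 2014-08-23, end: 2015-05-23}
      2015/16: {start: 2015-08-21, end: 2016-05-15}
      2016/17: {start: 2016-08-19, end: 2017-05-21}
  Ligue 1:
    seasons:
      2012/13: {start: 2012-08-10, end: 2013-05-26}
      2013/14: {start: 2013-08-09, end: 2014-05-17}
      2014/15: {start: 2014-08-08, end: 2015-05-23}
      2015/16: {start: 2015-08-07, end: 2016-05-14}
      2016/17: {start: 2016-08-12, end: 2017-05-20}
  Serie A:
    seasons:
      2012/13: {start: 2012-08-25, end: 2013-05-19}
      2013/14: {start: 2013-08-24, end: 2014-05-18}
      2014/15: {start: 2014-08-30, end: 2015-05-31}
      2015/16: {start: 2015-08-22, end: 2016-05-15}
      2016/17: {start: 2016-08-20, end: 2017-05-28}
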