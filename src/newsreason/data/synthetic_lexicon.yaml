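# Synthetic fixture lexicon: a small hand-written word -> categories map used
# as a pluggable stand-in sentiment scorer.  Category names follow the
# vocabulary common in politics/finance news headlines; scores produced from
# this lexicon are illustrative, not a trained sentiment resource.
war: [war, aggression, fight]
battle: [war, fight]
troops: [war, government]
attack: [aggression, fight]
attacks: [aggression, fight]
violence: [aggression]
clash: [fight, dispute]
fight: [fight]
conflict: [dispute, war]
dispute: [dispute]
row: [dispute]
feud: [dispute]
strong: [strength]
strength: [strength]
power: [power, strength]
powerful: [power, strength]
president: [politics, leader, government]
senator: [politics, government]
congress: [politics, government]
election: [politics]
vote: [politics]
campaign: [politics]
party: [politics]
policy: [politics, government, law]
government: [government]
federal: [government]
state: [government]
minister: [government, leader]
leader: [leader]
chief: [leader]
boss: [leader]
speech: [communication]
statement: [communication]
announce: [communication]
announces: [communication]
says: [communication]
said: [communication]
report: [communication]
travel: [traveling]
flight: [traveling]
border: [traveling, government]
visa: [traveling, law]
money: [money, economics]
cash: [money]
dollar: [money, economics]
dollars: [money, economics]
tax: [money, government, economics]
taxes: [money, government, economics]
bank: [banking, money]
banks: [banking, money]
banking: [banking]
loan: [banking, payment]
pay: [payment, money]
payment: [payment]
paid: [payment]
wage: [payment, economics]
rich: [wealthy]
wealthy: [wealthy]
billionaire: [wealthy, money]
millionaire: [wealthy, money]
fortune: [wealthy, valuable]
gold: [valuable, money]
valuable: [valuable]
worth: [valuable, money]
donate: [giving]
donates: [giving]
donation: [giving, money]
charity: [giving]
gift: [giving]
law: [law]
court: [law, government]
judge: [law]
illegal: [law]
ban: [law, government]
bans: [law, government]
economy: [economics]
economic: [economics]
market: [economics, money]
trade: [economics]
jobs: [economics]
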